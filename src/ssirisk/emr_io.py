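"""Cohort data model, file I/O, run configuration and summary statistics.

A cohort is a flat table with one row per inpatient record: structured
preoperative features in their natural units, one free-text preoperative
note, a binary SSI label, an optional NNIS risk-index score (0-3) and a
split tag (``development`` or ``test``).  Missing cells are represented by
a single sentinel (``numpy.nan``) for every feature kind, so downstream
missing-value indicator generation is deterministic.
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ssirisk")

#: reserved (non-structured) column names of a cohort table
RESERVED_COLUMNS = ("record_id", "note_text", "label", "nnis_score", "split")

SPLIT_DEVELOPMENT = "development"
SPLIT_TEST = "test"


class SchemaError(ValueError):
    """A cohort file does not match its feature schema."""


class IntegrityError(ValueError):
    """A cohort violates a structural invariant (e.g. duplicate ids)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with the half-up convention used for reported percentages."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One structured feature: a name, a kind and (for categoricals) labels."""

    name: str
    kind: str  # "continuous" | "binary" | "categorical"
    categories: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.categories:
            raise SchemaError(f"categorical feature {self.name!r} needs categories")


class FeatureSchema:
    """Ordered collection of :class:`Feature`, unique by name."""

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        overlap = set(names) & set(RESERVED_COLUMNS)
        if overlap:
            raise SchemaError(f"feature names collide with reserved columns: {overlap}")
        self._by_name = {f.name: f for f in self.features}

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def continuous(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "continuous"]

    @property
    def non_continuous(self) -> list[str]:
        return [f.name for f in self.features if f.kind != "continuous"]

    def __getitem__(self, name: str) -> Feature:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.features)

    def to_dict(self) -> list[dict]:
        return [dataclasses.asdict(f) for f in self.features]

    @classmethod
    def from_dict(cls, items: Sequence[dict]) -> "FeatureSchema":
        feats = []
        for it in items:
            cats = it.get("categories")
            feats.append(Feature(it["name"], it["kind"],
                                 tuple(cats) if cats else None, it.get("units", "")))
        return cls(feats)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

class CohortTable:
    """Per-patient records: structured features, note text, label, split.

    Thin wrapper over a :class:`pandas.DataFrame` that enforces the cohort
    invariants (unique record ids, binary labels, NNIS in 0-3) and keeps
    the feature schema alongside the data.
    """

    def __init__(self, df: pd.DataFrame, schema: FeatureSchema):
        df = df.copy()
        if "record_id" not in df.columns or "label" not in df.columns:
            raise SchemaError("cohort requires record_id and label columns")
        if df["record_id"].duplicated().any():
            dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
            raise IntegrityError(f"duplicate record_id {dup!r}")
        labels = df["label"].to_numpy()
        if not np.isin(labels[~pd.isna(labels)], [0, 1]).all():
            raise IntegrityError("labels must be 0/1")
        if "nnis_score" in df.columns:
            nnis = df["nnis_score"].dropna().to_numpy()
            if len(nnis) and not np.isin(nnis.astype(float), [0, 1, 2, 3]).all():
                raise IntegrityError("nnis_score must be in {0,1,2,3}")
        unknown = [c for c in df.columns
                   if c not in RESERVED_COLUMNS and c not in schema
                   and not c.endswith("__missing")]
        if unknown:
            raise SchemaError(f"columns not in schema: {unknown}")
        if "note_text" not in df.columns:
            df["note_text"] = ""
        if "split" not in df.columns:
            df["split"] = SPLIT_DEVELOPMENT
        df["record_id"] = df["record_id"].astype(str)
        df["label"] = df["label"].astype(int)
        for name in schema.continuous:
            if name in df.columns:
                df[name] = pd.to_numeric(df[name], errors="coerce")
        # categorical/binary cells are canonical strings (CSV readers may
        # have parsed "true"/"false" into booleans)
        def _canon(v):
            if pd.isna(v):
                return np.nan
            if isinstance(v, (bool, np.bool_)):
                return "true" if v else "false"
            return str(v)
        for name in schema.non_continuous:
            if name in df.columns:
                df[name] = df[name].map(_canon)
        self.df = df.reset_index(drop=True)
        self.schema = schema

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def record_ids(self) -> np.ndarray:
        return self.df["record_id"].to_numpy()

    def split(self, which: str) -> "CohortTable":
        """Return the sub-cohort whose split tag equals *which*."""
        sub = self.df[self.df["split"] == which]
        if sub.empty:
            raise IntegrityError(f"empty split {which!r}")
        return CohortTable(sub, self.schema)

    @property
    def development(self) -> "CohortTable":
        return self.split(SPLIT_DEVELOPMENT)

    @property
    def test(self) -> "CohortTable":
        return self.split(SPLIT_TEST)

    def notes_tokens(self, tokenizer=None) -> list[list[str]]:
        """Tokenised notes, whitespace by default; the tokenizer is pluggable."""
        tok = tokenizer or (lambda s: s.split())
        return [tok(t) if isinstance(t, str) else [] for t in self.df["note_text"]]

    def equals(self, other: "CohortTable") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            x, y = a[c], b[c]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                    return False
            else:
                xm, ym = x.isna(), y.isna()
                if not (xm == ym).all() or not (x[~xm] == y[~ym]).all():
                    return False
        return True


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a cohort from CSV (UTF-8, header row) or JSONL by extension.

    Missing cells (empty CSV cells, JSON nulls, absent keys) become the
    single ``nan`` sentinel.  Unknown columns raise :class:`SchemaError`;
    duplicate record ids raise :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".jsonl":
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, encoding="utf-8")
    df = df.replace({None: np.nan})
    if "note_text" in df.columns:
        df["note_text"] = df["note_text"].fillna("")
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write CSV or JSONL by extension; lossless round-trip with read_cohort."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in cohort.df.to_dict(orient="records"):
                clean = {k: (None if (isinstance(v, float) and np.isnan(v)) else v)
                         for k, v in rec.items()}
                fh.write(json.dumps(clean, ensure_ascii=False) + "\n")
    else:
        cohort.df.to_csv(path, index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    n: int
    n_positive: int
    incidence_pct: float
    category_percent: pd.DataFrame  # columns: feature, category, count, percent
    missing_rate_pct: pd.Series     # per structured feature, in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": "label", "category": "SSI", "count": self.n_positive,
                 "percent": self.incidence_pct}]
        rows += self.category_percent.to_dict(orient="records")
        return pd.DataFrame(rows)


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Counts, category percentages, per-feature missing rates and incidence.

    Incidence and percentages are ``100 * count / total`` rounded half-up
    to two decimals, matching the convention of published cohort tables.
    """
    df = cohort.df
    if df.empty:
        raise IntegrityError("empty cohort")
    n = len(df)
    n_pos = int(df["label"].sum())
    incidence = round_half_up(100.0 * n_pos / n)

    cat_rows = []
    for name in cohort.schema.non_continuous:
        if name not in df.columns:
            continue
        counts = df[name].value_counts(dropna=True)
        for cat, cnt in counts.items():
            cat_rows.append({"feature": name, "category": cat, "count": int(cnt),
                             "percent": round_half_up(100.0 * cnt / n)})
    cat_df = pd.DataFrame(cat_rows, columns=["feature", "category", "count", "percent"])

    miss = {}
    for name in cohort.schema.names:
        if name in df.columns:
            miss[name] = round_half_up(100.0 * df[name].isna().sum() / n)
    return CohortSummary(n, n_pos, incidence, cat_df, pd.Series(miss, dtype=float))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seeds, paths, hyperparameters and evaluation settings for a run.

    Defaults are the selected operating points of the reference study:
    e.g. L1 penalty 0.01 (with text) / 0.003 (without) for the logistic
    model, 256-channel CNN with windows 3/4/5, Bi-LSTM hidden size 256
    with attention layers 256/64, learning rate 1e-4 under AdamW,
    bootstrap of 100 iterations with 95% CIs.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    embedding_dim: int = 128
    subword_min_n: int = 2
    subword_max_n: int = 5
    bootstrap_iterations: int = 100
    ci_level: float = 0.95
    families: tuple[str, ...] = ("l1_logistic", "random_forest", "gbdt", "cnn", "self_attention")
    model_params: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    corpus: dict = field(default_factory=dict)
    reduced: bool = False

    def __post_init__(self):
        for name in ("embedding_dim", "subword_min_n", "subword_max_n", "bootstrap_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(d["families"])
        return d


class StageTimer:
    """Context manager logging per-stage wall time and the seed in use."""

    def __init__(self, stage: str, seed: int | None = None):
        self.stage, self.seed = stage, seed

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s started%s", self.stage,
                    f" (seed={self.seed})" if self.seed is not None else "")
        return self

    def __exit__(self, *exc):
        logger.info("stage %s finished in %.2fs", self.stage, time.perf_counter() - self.t0)
        return False
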