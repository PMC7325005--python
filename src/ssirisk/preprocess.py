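"""Preprocessing: outlier screen, missing indicators, imputation, encoding.

All statistics (imputation values, z-score moments, category lists,
outlier fits) are estimated on the development split only and applied
unchanged to the test split — the screen never peeks at held-out data.

The outlier screen is a two-stage adjusted-residual procedure: each
continuous feature is regressed on age and sex, residuals are
standardized by a robust SD (1.4826 x median absolute deviation, so that
outliers do not inflate their own yardstick), cells beyond the threshold
are excluded, the model is refitted on the retained rows and cells beyond
the threshold under the refit are flagged.  Flagged cells are listed,
never silently modified; ``apply_outlier_flags`` converts them to missing
on request, mirroring a workflow where flags that fail chart review are
treated as missing values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emr_io import CohortTable, FeatureSchema

logger = logging.getLogger("ssirisk")

MISSING_SUFFIX = "__missing"
_MAD_TO_SD = 1.4826


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Flagged cells: record_id, feature, value, standardized residual."""

    flags: pd.DataFrame  # columns: record_id, feature, value, residual
    skipped: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.flags.to_csv(path, index=False)
        return path

    def cells(self) -> set[tuple[str, str]]:
        return set(zip(self.flags["record_id"], self.flags["feature"]))


def _adjusted_residuals(vals, age, sex):
    X = np.column_stack([np.ones(len(age)), age, sex])
    beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
    return vals - X @ beta


def _robust_sd(resid: np.ndarray) -> float:
    return _MAD_TO_SD * float(np.median(np.abs(resid - np.median(resid))))


def detect_outliers(cohort: CohortTable, features: list[str] | None = None,
                    threshold: float = 5.0) -> OutlierReport:
    """Two-stage age/sex-adjusted residual screen on continuous features.

    Stage 1 fits ``feature ~ age + sex``, standardizes residuals by their
    robust SD and excludes cells with \\|r\\| > threshold; stage 2 refits on
    the retained rows and flags cells with \\|r\\| > threshold under the
    refit.  Features with fewer than 30 observed values are skipped with
    a warning.  Intended to run on the development split only.
    """
    df = cohort.df
    features = features or [f for f in cohort.schema.continuous if f != "age"]
    age = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
    sex = ((df["sex_male"] == "true").astype(float).to_numpy()
           if "sex_male" in df.columns else np.zeros(len(df)))
    rows, skipped = [], []
    for feat in features:
        vals = pd.to_numeric(df[feat], errors="coerce").to_numpy(dtype=float)
        obs = ~np.isnan(vals) & ~np.isnan(age)
        if obs.sum() < 30:
            skipped.append(feat)
            logger.warning("outlier screen skipped %s (<30 observed values)", feat)
            continue
        idx = np.flatnonzero(obs)
        r1 = _adjusted_residuals(vals[idx], age[idx], sex[idx])
        sd1 = _robust_sd(r1)
        tiny = 1e-10 * max(1.0, float(np.abs(vals[idx]).max()))
        if sd1 <= tiny:
            skipped.append(feat)
            logger.warning("outlier screen skipped %s (zero robust SD)", feat)
            continue
        keep = np.abs(r1 / sd1) <= threshold
        if keep.sum() < 30:
            skipped.append(feat)
            continue
        kidx = idx[keep]
        X_keep = np.column_stack([np.ones(len(kidx)), age[kidx], sex[kidx]])
        beta, *_ = np.linalg.lstsq(X_keep, vals[kidx], rcond=None)
        r2_all = vals[idx] - np.column_stack(
            [np.ones(len(idx)), age[idx], sex[idx]]) @ beta
        sd2 = _robust_sd(r2_all[keep])
        if sd2 <= tiny:
            skipped.append(feat)
            continue
        z = r2_all / sd2
        for i, zi in zip(idx, z):
            if abs(zi) > threshold:
                rows.append({"record_id": df.at[i, "record_id"], "feature": feat,
                             "value": float(vals[i]), "residual": float(zi)})
    flags = pd.DataFrame(rows, columns=["record_id", "feature", "value", "residual"])
    return OutlierReport(flags=flags, skipped=skipped)


def apply_outlier_flags(cohort: CohortTable, report: OutlierReport) -> CohortTable:
    """Convert flagged cells to missing (stand-in for failed chart review)."""
    df = cohort.df.copy()
    pos = {rid: i for i, rid in enumerate(df["record_id"])}
    for rid, feat in report.cells():
        if rid in pos:
            df.at[pos[rid], feat] = np.nan
    return CohortTable(df, cohort.schema)


# ---------------------------------------------------------------------------
# missing-value indicators
# ---------------------------------------------------------------------------

def add_missing_indicators(cohort: CohortTable,
                           reference: CohortTable | None = None) -> CohortTable:
    """Add one ``<feature>__missing`` binary column per feature with missing cells.

    Which features get an indicator is decided on the *reference* cohort
    (the development split; defaults to the cohort itself), so development
    and test acquire identical columns.  Indicators of indicators are
    never created; calling twice is a no-op.
    """
    ref = (reference or cohort).df
    df = cohort.df.copy()
    for name in cohort.schema.names:
        ind = name + MISSING_SUFFIX
        if ind in df.columns:
            continue
        if name in ref.columns and ref[name].isna().any():
            df[ind] = df[name].isna().astype(int)
    return CohortTable(df, cohort.schema)


# ---------------------------------------------------------------------------
# design-matrix transformer
# ---------------------------------------------------------------------------

@dataclass
class PreprocessStats:
    """Development-split statistics frozen for reuse at inference time."""

    cont_mean: dict
    cont_sd: dict
    modes: dict
    categories: dict       # feature -> list of development categories
    indicator_features: list
    dropped: list          # zero-variance continuous features
    normalize_all: bool = False

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessStats":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


class EMRPreprocessor:
    """Impute, encode and normalize a cohort into a numeric design matrix.

    sklearn-style transformer: ``fit`` on the development cohort, then
    ``transform`` any cohort with the frozen statistics.  Continuous
    features are mean-imputed and z-scored with development moments;
    binary/categorical features are mode-imputed and one-hot encoded over
    development categories (categories unseen in development map to an
    all-zero block with a logged warning).  Zero-variance continuous
    features are dropped with a warning.  Set ``normalize_all=True`` to
    also z-score indicator and one-hot columns.
    """

    def __init__(self, normalize_all: bool = False):
        self.normalize_all = normalize_all

    def get_params(self, deep=True):
        return {"normalize_all": self.normalize_all}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, cohort: CohortTable) -> "EMRPreprocessor":
        df, schema = cohort.df, cohort.schema
        cont_mean, cont_sd, modes, categories, dropped = {}, {}, {}, {}, []
        for name in schema.continuous:
            vals = pd.to_numeric(df[name], errors="coerce")
            mu = float(vals.mean()) if vals.notna().any() else 0.0
            sd = float(vals.std(ddof=0))
            if not np.isfinite(sd) or sd <= 0:
                dropped.append(name)
                logger.warning("dropping zero-variance feature %s", name)
                continue
            cont_mean[name], cont_sd[name] = mu, sd
        for name in schema.non_continuous:
            obs = df[name].dropna()
            modes[name] = (obs.mode().iloc[0] if not obs.empty
                           else schema[name].categories[0])
            categories[name] = sorted(obs.unique().tolist()) or [modes[name]]
        indicators = [c for c in df.columns if c.endswith(MISSING_SUFFIX)]
        self.stats_ = PreprocessStats(cont_mean, cont_sd, modes, categories,
                                      indicators, dropped, self.normalize_all)
        self.feature_names_out_ = self._column_names(cohort.schema)
        return self

    def _column_names(self, schema: FeatureSchema) -> list[str]:
        s = self.stats_
        names = [f for f in schema.continuous if f in s.cont_mean]
        for f in schema.non_continuous:
            names += [f"{f}={c}" for c in s.categories[f]]
        names += list(s.indicator_features)
        return names

    def transform(self, cohort: CohortTable) -> pd.DataFrame:
        if not hasattr(self, "stats_"):
            raise RuntimeError("EMRPreprocessor is not fitted")
        s, df, schema = self.stats_, cohort.df, cohort.schema
        out = {}
        for name in schema.continuous:
            if name not in s.cont_mean:
                continue
            vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
            vals = np.where(np.isnan(vals), s.cont_mean[name], vals)
            out[name] = (vals - s.cont_mean[name]) / s.cont_sd[name]
        for name in schema.non_continuous:
            vals = df[name].astype(object).where(df[name].notna(), s.modes[name])
            unseen = set(vals.unique()) - set(s.categories[name])
            if unseen:
                logger.warning("categories unseen in development for %s: %s "
                               "(all-zero one-hot block)", name, sorted(unseen))
            for cat in s.categories[name]:
                out[f"{name}={cat}"] = (vals == cat).astype(float).to_numpy()
        for ind in s.indicator_features:
            base = ind[:-len(MISSING_SUFFIX)]
            if ind in df.columns:
                out[ind] = df[ind].to_numpy(dtype=float)
            elif base in df.columns:  # recompute from raw missingness
                out[ind] = df[base].isna().to_numpy(dtype=float)
            else:
                out[ind] = np.zeros(len(df))
        mat = pd.DataFrame(out, columns=self.feature_names_out_,
                           index=range(len(df)))
        if s.normalize_all:
            for c in mat.columns:
                sd = mat[c].std(ddof=0)
                if sd > 0:
                    mat[c] = (mat[c] - mat[c].mean()) / sd
        assert not mat.isna().any().any()
        return mat

    def fit_transform(self, cohort: CohortTable) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)


def fit_transform(cohort_dev: CohortTable, cohort_test: CohortTable | None = None,
                  normalize_all: bool = False):
    """Fit on development, apply to both splits; returns matrices + stats.

    Missing-value indicators are added (decided on the development split)
    before fitting, so the missingness pattern survives imputation.
    """
    dev = add_missing_indicators(cohort_dev)
    prep = EMRPreprocessor(normalize_all=normalize_all)
    X_dev = prep.fit_transform(dev)
    X_test = None
    if cohort_test is not None:
        missing_feats = [f for f in cohort_test.schema.names
                         if f not in cohort_dev.schema]
        if missing_feats:
            raise ValueError(f"test features absent from development schema: {missing_feats}")
        test = add_missing_indicators(cohort_test, reference=dev)
        X_test = prep.transform(test)
    return X_dev, X_test, prep.stats_
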