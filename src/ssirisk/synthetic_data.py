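"""Synthetic EMR cohorts and corpora with the structure the pipeline assumes.

Real preoperative EMR extracts are private, so this module generates
cohorts whose statistics mirror the target setting: a rare binary outcome
(default prevalence 1.1%), 47 structured preoperative features with
per-feature missingness between 0% and 73%, and free-text notes whose
keywords carry risk signal independent of the structured features.

Labels are drawn from a logistic model

    logit(p) = b + sum_j beta_j * z_j  + sum_k gamma_k * 1[keyword_k in note]

where ``z_j`` are z-scored structured features and the intercept ``b`` is
calibrated by bisection so the empirical prevalence matches the target.
A truth sidecar records every planted effect for downstream assertions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emr_io import (
    CohortTable,
    Feature,
    FeatureSchema,
    SPLIT_DEVELOPMENT,
    SPLIT_TEST,
)


class CalibrationError(RuntimeError):
    """The target prevalence cannot be reached by shifting the intercept."""


class SpecError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# default feature panel: 47 structured preoperative features
# (mean, sd, age slope per decade in SDs, male shift in SDs, missing rate)
# ---------------------------------------------------------------------------

_LAB_PANEL: dict[str, tuple[float, float, float, float, float]] = {
    # demographics / anthropometrics
    "age": (54.0, 15.0, 0.0, 0.0, 0.0),
    "height_cm": (165.0, 8.0, -0.05, 0.9, 0.02),
    "weight_kg": (63.0, 11.0, 0.0, 0.5, 0.03),
    # routine blood examination
    "wbc": (6.3, 1.8, 0.0, 0.1, 0.05),
    "neut_pct": (60.0, 9.0, 0.05, 0.0, 0.05),
    "lymph_pct": (30.0, 8.0, -0.05, 0.0, 0.05),
    "mono_pct": (6.5, 1.8, 0.0, 0.1, 0.05),
    "eos_pct": (2.2, 1.5, 0.0, 0.0, 0.05),
    "baso_pct": (0.5, 0.3, 0.0, 0.0, 0.05),
    "lymph_count": (1.9, 0.6, -0.05, 0.0, 0.05),
    "mono_count": (0.42, 0.15, 0.0, 0.1, 0.05),
    "eos_count": (0.15, 0.1, 0.0, 0.0, 0.05),
    "rbc": (4.5, 0.5, -0.05, 0.6, 0.05),
    "hgb": (135.0, 16.0, -0.05, 0.8, 0.05),
    "mcv": (89.0, 5.0, 0.05, 0.0, 0.05),
    "mch": (30.0, 2.0, 0.0, 0.0, 0.05),
    "mchc": (335.0, 12.0, 0.0, 0.0, 0.05),
    "plt": (230.0, 55.0, -0.05, -0.2, 0.05),
    # coagulation
    "pt": (11.5, 0.9, 0.05, 0.0, 0.15),
    "inr": (1.0, 0.08, 0.05, 0.0, 0.15),
    "fib": (3.0, 0.7, 0.1, 0.0, 0.15),
    "aptt": (28.0, 3.5, 0.0, 0.0, 0.15),
    "tt": (17.0, 1.5, 0.0, 0.0, 0.15),
    "ddimer": (0.5, 0.6, 0.15, 0.0, 0.55),
    # liver and kidney function
    "tbil": (12.0, 5.0, 0.0, 0.2, 0.35),
    "dbil": (4.0, 1.8, 0.0, 0.1, 0.35),
    "tba": (4.5, 3.0, 0.0, 0.0, 0.40),
    "alt": (22.0, 12.0, 0.0, 0.3, 0.30),
    "ast": (23.0, 9.0, 0.05, 0.2, 0.30),
    "tp": (70.0, 5.5, -0.05, 0.0, 0.30),
    "alb": (43.0, 4.0, -0.1, 0.1, 0.30),
    "bun": (5.3, 1.5, 0.15, 0.2, 0.30),
    "cr": (68.0, 15.0, 0.1, 0.8, 0.30),
    "ua": (320.0, 80.0, 0.0, 0.7, 0.35),
    "glu": (5.3, 1.2, 0.1, 0.0, 0.30),
    # plasma electrolytes
    "k": (4.1, 0.35, 0.0, 0.0, 0.65),
    "na": (141.0, 2.5, 0.0, 0.0, 0.65),
    "ca": (2.3, 0.1, -0.05, 0.0, 0.70),
    "p": (1.15, 0.17, 0.0, -0.1, 0.73),
    "mg": (0.88, 0.08, 0.0, 0.0, 0.73),
    # length of stay before operation (days)
    "preop_los": (2.5, 2.2, 0.05, 0.0, 0.0),
}

_BINARY_FEATURES = {
    # name: (P(true), missing rate)
    "sex_male": (0.385, 0.0),
    "insured": (0.8, 0.01),
    "smoking": (0.18, 0.10),
    "emergency": (0.07, 0.0),
}

_CATEGORICAL_FEATURES = {
    "marital": (("married", "unmarried", "divorced"), (0.78, 0.17, 0.05), 0.12),
    "anesthesia": (("general", "tiva", "spinal", "epidural", "nerve_block", "local"),
                   (0.45, 0.15, 0.15, 0.12, 0.07, 0.06), 0.0),
}


def default_schema() -> FeatureSchema:
    """Schema of the default 47-feature preoperative panel."""
    feats = [Feature(n, "continuous", units="natural") for n in _LAB_PANEL]
    feats += [Feature(n, "binary", categories=("false", "true")) for n in _BINARY_FEATURES]
    feats += [Feature(n, "categorical", categories=cats)
              for n, (cats, _, _) in _CATEGORICAL_FEATURES.items()]
    return FeatureSchema(feats)


# default planted effects (log-odds per SD for structured, per presence for keywords)
DEFAULT_STRUCTURED_EFFECTS = {
    "age": 0.5, "preop_los": 0.5, "hgb": -0.4, "alb": -0.35,
    "glu": 0.3, "wbc": 0.25, "emergency": 0.4,
}
DEFAULT_RISK_KEYWORDS = {
    "malignant": 1.5, "colon": 1.5, "tuberculosis": 1.5,
    "transverse_colon": 1.5, "reoperation": 1.5, "contaminated": 1.5,
}
DEFAULT_PROTECTIVE_KEYWORDS = {"thyroid": -1.0, "laparoscope": -1.0}

_BACKGROUND_VOCAB_SIZE = 300
_CLINICAL_STEMS = [
    "incision", "suture", "drainage", "anesthesia", "prophylaxis", "asepsis",
    "hernia", "appendix", "gallbladder", "uterus", "ovary", "kidney", "ureter",
    "bladder", "prostate", "stomach", "duodenum", "spine", "femur", "biopsy",
    "resection", "repair", "ligation", "anastomosis", "scheduled", "elective",
    "antibiotic", "consent", "fasting", "hemostasis",
]


@dataclass
class CohortSpec:
    """Conditions of a generated cohort; defaults emulate the study setting."""

    n: int = 20000
    target_incidence: float = 0.0113
    structured_effects: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURED_EFFECTS))
    risk_keywords: dict = field(default_factory=lambda: dict(DEFAULT_RISK_KEYWORDS))
    protective_keywords: dict = field(default_factory=lambda: dict(DEFAULT_PROTECTIVE_KEYWORDS))
    keyword_prevalence: float = 0.2
    note_length_distribution: tuple = (120.0, 60.0)  # tokens, mean / sd
    missing_rates: dict | None = None     # None -> panel defaults
    mnar_features: list = field(default_factory=list)
    mnar_shift: float = 1.0               # added to missingness logit for positives
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_incidence < 0.5:
            raise SpecError("target_incidence must be in (0, 0.5)")
        if self.n < 100:
            raise SpecError("n must be >= 100")
        rates = self.missing_rates or {}
        if any(not 0 <= r < 1 for r in rates.values()):
            raise SpecError("missing_rates must be in [0, 1)")


@dataclass
class CohortTruth:
    """Planted ground truth for test assertions."""

    intercept: float
    structured_effects: dict
    keyword_effects: dict
    keyword_prevalence: float
    outlier_mask: list  # (record_id, feature, original_value)
    true_logit: np.ndarray | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        d["true_logit"] = None
        path.write_text(json.dumps(d, indent=2), encoding="utf-8")
        return path


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(signal: np.ndarray, target: float, max_steps: int = 60) -> float:
    """Bisection for b with mean(sigmoid(b + signal)) == target."""
    lo, hi = -30.0, 30.0
    if _sigmoid(lo + signal).mean() > target or _sigmoid(hi + signal).mean() < target:
        raise CalibrationError("target incidence unreachable for planted effects")
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + signal).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _background_vocab() -> list[str]:
    vocab = list(_CLINICAL_STEMS)
    i = 0
    while len(vocab) < _BACKGROUND_VOCAB_SIZE:
        vocab.append(f"term{i:04d}")
        i += 1
    return vocab


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, CohortTruth]:
    """Generate a cohort table plus its truth sidecar.

    Order of operations: draw complete structured features, draw notes with
    planted keywords, compute true logits and calibrate the intercept, draw
    labels, inject outliers (if requested), then apply missingness.  The
    first 80% of records (generation order) are tagged ``development``,
    the rest ``test``, standing in for a temporal split.
    """
    rng = np.random.default_rng(spec.seed)
    schema = default_schema()
    n = spec.n

    # --- structured features (complete) ---
    age = np.clip(rng.normal(*_LAB_PANEL["age"][:2], size=n), 18, 95)
    male = (rng.random(n) < _BINARY_FEATURES["sex_male"][0]).astype(float)
    cols: dict[str, np.ndarray] = {"age": age}
    for name, (mu, sd, age_slope, male_shift, _miss) in _LAB_PANEL.items():
        if name == "age":
            continue
        vals = (mu
                + age_slope * sd * (age - 54.0) / 10.0
                + male_shift * sd * male
                + rng.normal(0.0, sd, size=n))
        if name == "preop_los":
            vals = np.clip(np.round(np.abs(vals)), 0, None)
        cols[name] = vals
    bin_cols: dict[str, np.ndarray] = {"sex_male": male}
    for name, (p, _miss) in _BINARY_FEATURES.items():
        if name == "sex_male":
            continue
        bin_cols[name] = (rng.random(n) < p).astype(float)
    cat_cols: dict[str, np.ndarray] = {}
    for name, (cats, probs, _miss) in _CATEGORICAL_FEATURES.items():
        cat_cols[name] = rng.choice(cats, size=n, p=probs)

    # --- notes ---
    vocab = _background_vocab()
    keywords = {**spec.risk_keywords, **spec.protective_keywords}
    mean_len, sd_len = spec.note_length_distribution
    lengths = np.maximum(5, np.round(rng.normal(mean_len, sd_len, size=n))).astype(int)
    # Zipf-ish background frequencies
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    bg_p = (1.0 / ranks) / (1.0 / ranks).sum()
    kw_names = list(keywords)
    kw_present = rng.random((n, len(kw_names))) < spec.keyword_prevalence
    notes = []
    for i in range(n):
        toks = list(rng.choice(vocab, size=lengths[i], p=bg_p))
        for j, kw in enumerate(kw_names):
            if kw_present[i, j]:
                for _ in range(int(rng.integers(1, 3))):
                    toks.insert(int(rng.integers(0, len(toks) + 1)), kw)
        notes.append(" ".join(toks))

    # --- true logit and labels ---
    signal = np.zeros(n)
    for feat, beta in spec.structured_effects.items():
        if feat in cols:
            v = cols[feat]
        elif feat in bin_cols:
            v = bin_cols[feat]
        elif "=" in feat and feat.split("=")[0] in cat_cols:
            fname, cat = feat.split("=", 1)
            v = (cat_cols[fname] == cat).astype(float)
        else:
            raise SpecError(f"unknown feature in structured_effects: {feat!r}")
        sd = v.std()
        if sd > 0:
            signal += beta * (v - v.mean()) / sd
    for j, kw in enumerate(kw_names):
        signal += keywords[kw] * kw_present[:, j]
    intercept = _calibrate_intercept(signal, spec.target_incidence)
    true_logit = intercept + signal
    labels = (rng.random(n) < _sigmoid(true_logit)).astype(int)

    # --- NNIS-like baseline score: coarse discretization of a noisy logit ---
    z = (true_logit - true_logit.mean()) / true_logit.std()
    nnis_latent = 0.45 * z + rng.normal(0, 1, size=n)
    qs = np.quantile(nnis_latent, [0.5, 0.8, 0.95])
    nnis = np.digitize(nnis_latent, qs).astype(int)

    # --- assemble frame ---
    df = pd.DataFrame({"record_id": [f"R{i:06d}" for i in range(n)]})
    for name in _LAB_PANEL:
        df[name] = cols[name]
    for name in _BINARY_FEATURES:
        df[name] = np.where(bin_cols[name] > 0.5, "true", "false")
    for name in _CATEGORICAL_FEATURES:
        df[name] = cat_cols[name]
    df["note_text"] = notes
    df["label"] = labels
    df["nnis_score"] = nnis
    n_dev = int(round(0.8 * n))
    df["split"] = [SPLIT_DEVELOPMENT] * n_dev + [SPLIT_TEST] * (n - n_dev)

    cohort = CohortTable(df, schema)
    truth = CohortTruth(
        intercept=float(intercept),
        structured_effects=dict(spec.structured_effects),
        keyword_effects=dict(keywords),
        keyword_prevalence=spec.keyword_prevalence,
        outlier_mask=[],
        true_logit=true_logit,
    )

    # --- outliers before missingness, so masked cells stay observable ---
    if spec.outlier_rate > 0:
        cohort, mask = inject_outliers(cohort, spec.outlier_rate,
                                       spec.outlier_magnitude_sd,
                                       seed=int(rng.integers(2**31)))
        truth.outlier_mask = mask

    # --- missingness ---
    rates = dict(spec.missing_rates) if spec.missing_rates is not None else None
    df = cohort.df
    for name in schema.names:
        if rates is not None:
            rate = rates.get(name, 0.0)
        elif name in _LAB_PANEL:
            rate = _LAB_PANEL[name][4]
        elif name in _BINARY_FEATURES:
            rate = _BINARY_FEATURES[name][1]
        else:
            rate = _CATEGORICAL_FEATURES[name][2]
        if rate <= 0:
            continue
        if name in spec.mnar_features:
            base_logit = np.log(rate / (1 - rate))
            p_miss = _sigmoid(base_logit + spec.mnar_shift * labels)
        else:
            p_miss = np.full(n, rate)
        miss = rng.random(n) < p_miss
        df.loc[miss, name] = np.nan
    return CohortTable(df, schema), truth


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

@dataclass
class CorpusSpec:
    """A synthetic pre-training corpus with planted co-occurrence clusters."""

    vocabulary_size: int = 200
    n_sentences: int = 2000
    clusters: tuple = ()            # tuples of tokens that co-occur
    cluster_prob: float = 0.5       # P(a sentence is built around a cluster)
    co_occur_prob: float = 0.95     # P(all cluster tokens appear together)
    mean_background: float = 8.0    # Poisson mean of background tokens/sentence
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 100:
            raise SpecError("n_sentences must be >= 100")
        flat = [t for c in self.clusters for t in c]
        if len(flat) != len(set(flat)):
            raise SpecError("clusters must be disjoint")
        if len(flat) > self.vocabulary_size:
            raise SpecError("vocabulary smaller than total cluster tokens")


def generate_corpus(spec: CorpusSpec) -> list[list[str]]:
    """Token sequences in which cluster members co-occur far above chance."""
    rng = np.random.default_rng(spec.seed)
    cluster_tokens = {t for c in spec.clusters for t in c}
    n_bg = spec.vocabulary_size - len(cluster_tokens)
    background = [f"bg{i:04d}" for i in range(n_bg)]
    sentences = []
    for _ in range(spec.n_sentences):
        toks: list[str] = []
        if spec.clusters and rng.random() < spec.cluster_prob:
            cluster = spec.clusters[int(rng.integers(len(spec.clusters)))]
            if rng.random() < spec.co_occur_prob:
                toks.extend(cluster)
            else:
                toks.append(cluster[int(rng.integers(len(cluster)))])
        k = int(rng.poisson(spec.mean_background)) + 1
        if background:
            toks.extend(rng.choice(background, size=k))
        toks = list(map(str, toks))
        rng.shuffle(toks)
        sentences.append(toks)
    return sentences


# ---------------------------------------------------------------------------
# outlier injection
# ---------------------------------------------------------------------------

def inject_outliers(cohort: CohortTable, rate: float, magnitude_sd: float = 8.0,
                    seed: int = 0) -> tuple[CohortTable, list]:
    """Shift randomly chosen continuous cells by ``magnitude_sd`` residual SDs.

    Residual SDs come from a per-feature fit against age and sex, the same
    adjustment the outlier screen uses, so an injected cell of magnitude 8
    stands at |standardized residual| ~ 8 under the detection model.  Age
    and sex themselves are never perturbed.  Returns the perturbed cohort
    and the truth mask of (record_id, feature, original_value).
    """
    df = cohort.df.copy()
    features = [f for f in cohort.schema.continuous if f != "age" and f in df.columns]
    if not features:
        raise SpecError("no continuous features to perturb")
    rng = np.random.default_rng(seed)
    n_cells = sum(int(df[f].notna().sum()) for f in features)
    if rate <= 0 or rate * n_cells < 1:
        if rate > 0:
            warnings.warn("outlier rate too small for any cell; no-op")
        return CohortTable(df, cohort.schema), []

    age = pd.to_numeric(df.get("age"), errors="coerce").to_numpy(dtype=float)
    sex = (df.get("sex_male") == "true").astype(float).to_numpy() \
        if "sex_male" in df.columns else np.zeros(len(df))
    mask: list = []
    for feat in features:
        vals = df[feat].to_numpy(dtype=float)
        obs = ~np.isnan(vals) & ~np.isnan(age)
        if obs.sum() < 30:
            continue
        X = np.column_stack([np.ones(obs.sum()), age[obs], sex[obs]])
        beta, *_ = np.linalg.lstsq(X, vals[obs], rcond=None)
        resid_sd = np.std(vals[obs] - X @ beta)
        if resid_sd <= 0:
            continue
        idx = np.flatnonzero(obs)
        chosen = idx[rng.random(len(idx)) < rate]
        for i in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mask.append((df.at[i, "record_id"], feat, float(vals[i])))
            df.at[i, feat] = float(vals[i] + sign * magnitude_sd * resid_sd)
    return CohortTable(df, cohort.schema), mask
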