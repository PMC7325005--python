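"""Internal bootstrap validation, model comparison and operating points.

Internal validity follows the out-of-bag bootstrap protocol: in each of
(default) 100 iterations the model pipeline is refitted — preprocessing
statistics included, so no iteration sees its own held-out rows — on an
n-with-replacement resample of the development split and scored on the
records the resample missed.  Model families are compared by
paired-sample t-tests across the iteration-aligned AUROC vectors (the
resamples overlap, so the pairs are not independent; the test is the
conventional protocol, reported as such).  External validity is a single
evaluation of the fully trained model on the held-out test split, with
the operating point chosen by Youden's index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ssirisk")


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """AUROC as the Mann-Whitney U statistic / (N+ * N-), ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# bootstrap validation
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    aurocs: np.ndarray          # one out-of-bag AUROC per iteration
    oob_fractions: np.ndarray   # |out-of-bag| / n per iteration
    seed: int
    n: int

    def __post_init__(self):
        self.aurocs = np.asarray(self.aurocs, dtype=float)
        if ((self.aurocs < 0) | (self.aurocs > 1)).any():
            raise ValueError("AUROC outside [0,1]")


def bootstrap_validate(cohort_dev, pipeline_factory, iterations: int = 100,
                       seed: int = 0, max_redraws: int = 10) -> BootstrapResult:
    """Out-of-bag bootstrap of a full fit/score pipeline.

    ``pipeline_factory()`` must return an object with ``fit(cohort)`` and
    ``score(cohort) -> scores``; it is refitted from scratch inside each
    iteration so every statistic (imputation means, embeddings pooling,
    model weights) is re-estimated on the resample only.  Iterations whose
    resample or out-of-bag set is single-class are redrawn (at most
    *max_redraws* times, logged).
    """
    from .emr_io import CohortTable

    n = len(cohort_dev)
    labels = cohort_dev.labels
    rng = np.random.default_rng(seed)
    aurocs, fracs = [], []
    for it in range(iterations):
        for attempt in range(max_redraws + 1):
            inbag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), inbag)
            if (len(np.unique(labels[inbag])) == 2
                    and len(np.unique(labels[oob])) == 2):
                break
            logger.info("bootstrap iteration %d redrawn (single-class draw)", it)
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        df_in = cohort_dev.df.iloc[inbag].copy()
        df_in["record_id"] = [f"{r}#{k}" for k, r in enumerate(df_in["record_id"])]
        cohort_in = CohortTable(df_in, cohort_dev.schema)
        cohort_oob = CohortTable(cohort_dev.df.iloc[oob], cohort_dev.schema)
        pipe = pipeline_factory()
        pipe.fit(cohort_in)
        aurocs.append(auroc(pipe.score(cohort_oob), labels[oob]))
        fracs.append(len(oob) / n)
    return BootstrapResult(np.array(aurocs), np.array(fracs), seed, n)


def summarize_bootstrap(result: BootstrapResult, level: float = 0.95,
                        method: str = "t") -> tuple[float, tuple[float, float]]:
    """Mean AUROC and CI over bootstrap iterations.

    Default CI is the t-interval mean +/- t_{1-(1-level)/2, k-1} * sd/sqrt(k);
    ``method='percentile'`` gives the empirical percentile interval.
    """
    a = np.asarray(result.aurocs if isinstance(result, BootstrapResult) else result,
                   dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 iterations")
    mean = float(a.mean())
    if method == "percentile":
        lo, hi = np.quantile(a, [(1 - level) / 2, 1 - (1 - level) / 2])
        return mean, (float(lo), float(hi))
    sd = float(a.std(ddof=1))
    if sd == 0:
        return mean, (mean, mean)
    half = stats.t.ppf(1 - (1 - level) / 2, len(a) - 1) * sd / np.sqrt(len(a))
    return mean, (mean - half, mean + half)


def paired_t_test(aurocs_a, aurocs_b) -> tuple[float, float]:
    """Paired-sample t-test on iteration-aligned AUROC vectors.

    Degenerate zero-variance differences use the convention p=1 when the
    mean difference is 0 and p=0 otherwise.
    """
    a = np.asarray(aurocs_a, dtype=float)
    b = np.asarray(aurocs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 2:
        raise ValueError("need at least 2 paired iterations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        return (np.inf if d.mean() != 0 else 0.0,
                0.0 if d.mean() != 0 else 1.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------

@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    j: float

    def __post_init__(self):
        assert abs(self.j - (self.sensitivity + self.specificity - 1)) < 1e-9


def youden_cutoff(scores, labels) -> OperatingPoint:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Every distinct score is tried as a threshold with the convention
    'score >= t is positive'; ties in J resolve to the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)  # ascending
    best = None
    for t in thresholds:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best.j + 1e-12:
            best = OperatingPoint(float(t), float(sens), float(spec), float(j))
    return best


# ---------------------------------------------------------------------------
# external evaluation
# ---------------------------------------------------------------------------

@dataclass
class ExternalReport:
    auroc: float
    roc_points: pd.DataFrame          # columns: fpr, tpr, threshold
    operating_point: OperatingPoint
    nnis_auroc: float | None = None
    per_model: dict = field(default_factory=dict)


def external_evaluate(scores, labels, nnis_scores=None) -> ExternalReport:
    """Held-out evaluation: AUROC, ROC curve and Youden operating point.

    When an NNIS risk-index column is provided it is evaluated as the
    baseline comparator on the same records.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) == 0:
        raise ValueError("empty test split")
    fpr, tpr, thr = roc_curve(labels, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    report = ExternalReport(
        auroc=auroc(scores, labels),
        roc_points=roc,
        operating_point=youden_cutoff(scores, labels),
    )
    if nnis_scores is not None:
        nnis = np.asarray(nnis_scores, dtype=float)
        ok = ~np.isnan(nnis)
        if len(np.unique(labels[ok])) == 2:
            report.nnis_auroc = auroc(nnis[ok], labels[ok])
    return report
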