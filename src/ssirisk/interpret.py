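"""Model explanation: population-level coefficients and case-level word maps.

Population level: the ranked nonzero coefficients of the without-text
L1-penalised logistic model trained on the normalized design matrix
(missing-value indicators included) describe each structured feature's
direction and relative contribution.

Case level: a local surrogate.  Holding the structured features fixed,
the note's tokens are randomly dropped (each kept independently with
probability 0.5), the black-box model scores the perturbed notes, and an
L1-penalised linear regression of the scores on the binary
token-presence vectors yields one signed coefficient per token position
— positive means risk-increasing (rendered red), negative protective
(green).
"""

from __future__ import annotations

import dataclasses
import html
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso


def population_coefficients(l1_model, feature_names) -> pd.DataFrame:
    """Nonzero model coefficients ranked by absolute value, signed.

    ``l1_model`` is a fitted L1 logistic model (a
    :class:`~ssirisk.risk_models.ConventionalRiskModel` or any estimator
    exposing ``coef_``); the design must have been normalized so the
    coefficients are comparable across features.
    """
    try:
        coefs = np.asarray(l1_model.coef_).ravel()
    except AttributeError as exc:
        raise ValueError("model is not fitted") from exc
    if len(coefs) != len(feature_names):
        raise ValueError("feature_names length does not match coefficients")
    df = pd.DataFrame({"feature": list(feature_names), "coefficient": coefs})
    df = df[df["coefficient"] != 0.0]
    df = df.reindex(df["coefficient"].abs().sort_values(ascending=False).index)
    return df.reset_index(drop=True)


@dataclass
class ContributionMap:
    """Per-token signed contributions to one case's risk score."""

    tokens: list
    coefficients: np.ndarray
    intercept: float
    seed: int
    n_perturbations: int

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        assert len(self.coefficients) == len(self.tokens)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        d["coefficients"] = [float(c) for c in self.coefficients]
        path.write_text(json.dumps(d, indent=2, ensure_ascii=False), encoding="utf-8")
        return path


def case_word_contributions(scorer, tokens: list[str], n_perturb: int = 10_000,
                            l1: float = 0.01, keep_prob: float = 0.5,
                            seed: int = 0, batch: int = 2048) -> ContributionMap:
    """Local-surrogate word contributions for one note.

    ``scorer`` maps a list of token sequences to risk scores (structured
    features must already be held fixed inside it; see
    :func:`deep_case_scorer`).  Each perturbation keeps every token
    independently with probability *keep_prob*; an L1 regression of the
    scores on the presence indicators (1 = kept) gives per-position
    coefficients.  Deterministic under a fixed seed.
    """
    if not tokens:
        raise ValueError("note has no tokens")
    rng = np.random.default_rng(seed)
    presence = (rng.random((n_perturb, len(tokens))) < keep_prob).astype(float)
    scores = np.empty(n_perturb)
    for s in range(0, n_perturb, batch):
        block = presence[s:s + batch]
        seqs = [[t for t, keep in zip(tokens, row) if keep] for row in block]
        scores[s:s + batch] = np.asarray(scorer(seqs), dtype=float)
    if np.allclose(scores, scores[0]):
        warnings.warn("model score is constant under perturbation; "
                      "all contributions zero")
        return ContributionMap(list(tokens), np.zeros(len(tokens)),
                               float(scores[0]), seed, n_perturb)
    reg = Lasso(alpha=l1, fit_intercept=True, max_iter=5000)
    reg.fit(presence, scores)
    return ContributionMap(list(tokens), reg.coef_.copy(),
                           float(reg.intercept_), seed, n_perturb)


def deep_case_scorer(model, x_struct_row):
    """Freeze one record's structured features into a batch note scorer.

    Perturbed sequences are re-padded inside the model, so the network
    always sees valid shapes.
    """
    x = np.asarray(x_struct_row, dtype=np.float32).ravel()

    def scorer(note_batches):
        X = np.tile(x, (len(note_batches), 1))
        return model.predict_proba(X, note_batches)[:, 1]

    return scorer


def _color(coef: float, max_abs: float) -> str:
    if max_abs <= 0:
        return "#ffffff"
    x = max(-1.0, min(1.0, coef / max_abs))
    if x >= 0:  # white -> red
        g = b = int(round(255 * (1 - x)))
        return f"#ff{g:02x}{b:02x}"
    r = g2 = int(round(255 * (1 + x)))  # white -> green
    return f"#{r:02x}ff{g2:02x}"


def render_heatmap(contribution_map: ContributionMap, output_path) -> Path:
    """Standalone HTML heatmap: red = risk word, green = protective word.

    Color intensity is proportional to \\|coefficient\\| normalized by the
    map's maximum absolute coefficient.
    """
    path = Path(output_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    max_abs = float(np.max(np.abs(contribution_map.coefficients))) \
        if len(contribution_map.coefficients) else 0.0
    spans = []
    for tok, coef in zip(contribution_map.tokens, contribution_map.coefficients):
        spans.append(
            f'<span title="{coef:+.4f}" style="background:{_color(coef, max_abs)};'
            f'padding:1px 3px;margin:1px;border-radius:3px;display:inline-block">'
            f"{html.escape(str(tok))}</span>")
    doc = ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
           "<title>word contributions</title></head>"
           "<body style='font-family:sans-serif;line-height:1.9'>"
           + " ".join(spans) + "</body></html>")
    path.write_text(doc, encoding="utf-8")
    return path
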