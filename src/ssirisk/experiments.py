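"""Reproducible desk-scale experiment drivers.

These functions bundle the standard evaluation experiments the package
ships — signal recovery on planted-keyword cohorts, outlier-screen
operating characteristics, and local-surrogate fidelity — so the test
suite and the reproduction script exercise exactly the same protocol.

The planted-signal study conditions: cohorts of n = 8,000 records at 5%
prevalence (enough positives for stable single-split AUROC estimates at
this n), with the generator's default planted effects — six risk
keywords at +1.5 log-odds and two protective keywords at -1.0, each
present in 20% of notes independently, on top of the default structured
effects.  Embeddings are pre-trained on a synthetic co-occurrence corpus
built around the same keywords, then the reduced-size model families are
trained on the development split and scored on the held-out 20%.
"""

from __future__ import annotations

import numpy as np

from .embeddings import train_embeddings
from .preprocess import EMRPreprocessor, add_missing_indicators
from .risk_models import (
    AttentiveBiLSTMClassifier,
    ConventionalRiskModel,
    TextCNNClassifier,
    pooled_text_matrix,
)
from .synthetic_data import (
    CohortSpec,
    CorpusSpec,
    generate_cohort,
    generate_corpus,
    inject_outliers,
)
from .validation import auroc

from .synthetic_data import DEFAULT_PROTECTIVE_KEYWORDS, DEFAULT_RISK_KEYWORDS

RISK_KEYWORDS = dict(DEFAULT_RISK_KEYWORDS)
PROTECTIVE_KEYWORDS = dict(DEFAULT_PROTECTIVE_KEYWORDS)

#: reduced-size deep configurations for single-CPU runs
REDUCED_CNN = dict(channels=8, dense_units=32, epochs=5, lr=2e-3,
                   batch_size=128, dropout_conv=0.1, dropout_dense=0.1)
REDUCED_ATTN = dict(m=16, d1=32, d2=4, dense_units=32, epochs=8, lr=5e-3,
                    batch_size=128, dropout_emb=0.2, dropout_lstm=0.2,
                    weight_decay=0.1, early_stopping=True, patience=3,
                    validation_fraction=0.15)


def planted_cohort_spec(seed: int, n: int = 8000) -> CohortSpec:
    return CohortSpec(n=n, target_incidence=0.05, seed=seed,
                      risk_keywords=dict(RISK_KEYWORDS),
                      protective_keywords=dict(PROTECTIVE_KEYWORDS),
                      keyword_prevalence=0.2)


def keyword_corpus(seed: int, n_sentences: int = 800):
    """Pre-training corpus whose co-occurrence clusters carry the keywords."""
    kws = list(RISK_KEYWORDS) + list(PROTECTIVE_KEYWORDS)
    clusters = tuple((k, f"{k}x1") for k in kws)
    return generate_corpus(CorpusSpec(vocabulary_size=40 + 2 * len(kws) + 160,
                                      n_sentences=n_sentences,
                                      clusters=clusters, seed=seed))


def prepare_splits(seed: int, n: int = 8000):
    """Cohort + frozen design matrices + tokenised notes + embeddings."""
    cohort, truth = generate_cohort(planted_cohort_spec(seed, n))
    dev, test = cohort.development, cohort.test
    devi = add_missing_indicators(dev)
    prep = EMRPreprocessor().fit(devi)
    X_dev = prep.transform(devi).to_numpy(dtype=np.float32)
    X_test = prep.transform(test).to_numpy(dtype=np.float32)
    table = train_embeddings(keyword_corpus(seed), d=32, epochs=6, seed=seed)
    return dict(cohort=cohort, truth=truth, dev=dev, test=test,
                X_dev=X_dev, X_test=X_test,
                y_dev=dev.labels, y_test=test.labels,
                notes_dev=dev.notes_tokens(), notes_test=test.notes_tokens(),
                table=table, prep=prep)


def conventional_text_benefit(splits: dict, seed: int,
                              families=("l1_logistic", "random_forest", "gbdt")
                              ) -> dict[str, tuple[float, float]]:
    """Held-out AUROC (without text, with text) per conventional family."""
    P_dev = pooled_text_matrix(splits["notes_dev"], splits["table"])
    P_test = pooled_text_matrix(splits["notes_test"], splits["table"])
    Xd_text = np.hstack([splits["X_dev"], P_dev])
    Xt_text = np.hstack([splits["X_test"], P_test])
    out = {}
    for family in families:
        m0 = ConventionalRiskModel(family, use_text=False, seed=seed)
        m0.fit(splits["X_dev"], splits["y_dev"])
        a0 = auroc(m0.predict_proba(splits["X_test"])[:, 1], splits["y_test"])
        m1 = ConventionalRiskModel(family, use_text=True, seed=seed)
        m1.fit(Xd_text, splits["y_dev"])
        a1 = auroc(m1.predict_proba(Xt_text)[:, 1], splits["y_test"])
        out[family] = (a0, a1)
    return out


def deep_heldout_auroc(splits: dict, seed: int,
                       families=("cnn", "self_attention")) -> dict[str, float]:
    """Held-out AUROC of the reduced-size deep families."""
    out = {}
    for family in families:
        if family == "cnn":
            model = TextCNNClassifier(embedding_table=splits["table"],
                                      seed=seed, **REDUCED_CNN)
        else:
            model = AttentiveBiLSTMClassifier(embedding_table=splits["table"],
                                              seed=seed, **REDUCED_ATTN)
        model.fit(splits["X_dev"], splits["notes_dev"], splits["y_dev"])
        scores = model.predict_proba(splits["X_test"], splits["notes_test"])[:, 1]
        out[family] = auroc(scores, splits["y_test"])
    return out


def outlier_screen_metrics(seed: int, n: int = 4000,
                           rate: float = 0.002, magnitude: float = 8.0):
    """(recall on injected cells, false-flag rate on clean cells)."""
    from .preprocess import detect_outliers

    cohort, _ = generate_cohort(CohortSpec(n=n, seed=seed, missing_rates={}))
    shifted, mask = inject_outliers(cohort, rate, magnitude, seed=seed + 1)
    flagged = detect_outliers(shifted, threshold=5.0).cells()
    injected = {(r, f) for r, f, _ in mask}
    recall = len(injected & flagged) / len(injected)
    clean_flags = len(flagged - injected)
    n_clean_cells = sum(int(shifted.df[f].notna().sum())
                        for f in shifted.schema.continuous) - len(injected)
    return recall, clean_flags / n_clean_cells


def surrogate_fidelity(n_perturb: int = 10000, seed: int = 0):
    """Max relative error of recovered weights for an additive token scorer,
    plus whether the planted risk keyword ranks first by |coefficient|."""
    from .interpret import case_word_contributions

    weights = {"kw_malignant": 0.30, "kw_colon": 0.15, "thyroid": -0.20}
    tokens = ["incision", "kw_malignant", "suture", "kw_colon", "drainage",
              "thyroid", "consent", "fasting", "asepsis", "hernia"]

    def scorer(batches):
        return np.array([0.2 + sum(w for t, w in weights.items() if t in seq)
                         for seq in batches])

    cmap = case_word_contributions(scorer, tokens, n_perturb=n_perturb,
                                   l1=1e-4, seed=seed)
    coefs = dict(zip(cmap.tokens, cmap.coefficients))
    rel_errors = [abs(coefs[t] - w) / abs(w) for t, w in weights.items()]
    top_token = max(coefs, key=lambda t: abs(coefs[t]))
    return max(rel_errors), top_token == "kw_malignant"
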