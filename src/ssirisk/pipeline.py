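"""End-to-end fit/score pipelines: preprocessing + text features + model.

A :class:`RiskPipeline` bundles one model family with everything it
needs to go from a raw cohort split to risk scores — missing-value
indicators, development-only imputation/normalization statistics, pooled
or sequential text features, and the fitted predictor.  Because the
whole bundle refits from scratch on whatever cohort ``fit`` receives, it
is the unit the out-of-bag bootstrap resamples without leakage.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingTable
from .emr_io import CohortTable, FeatureSchema
from .preprocess import EMRPreprocessor, PreprocessStats, add_missing_indicators
from .risk_models import (
    CONVENTIONAL_FAMILIES,
    DEEP_FAMILIES,
    AttentiveBiLSTMClassifier,
    ConventionalRiskModel,
    TextCNNClassifier,
    pooled_text_matrix,
    train_deep,
)

#: reduced-size settings for desk-scale runs (documented in the methods note)
REDUCED_DEEP_PARAMS = {
    "cnn": {"channels": 8, "dense_units": 32, "epochs": 5, "lr": 2e-3,
            "batch_size": 128, "dropout_conv": 0.1, "dropout_dense": 0.1},
    "self_attention": {"m": 16, "d1": 32, "d2": 4, "dense_units": 32,
                       "epochs": 5, "lr": 5e-3, "batch_size": 128,
                       "dropout_emb": 0.1, "dropout_lstm": 0.1},
}


class RiskPipeline:
    """One family's full preprocessing + training + scoring pipeline."""

    def __init__(self, family: str, use_text: bool = False,
                 embedding_table: EmbeddingTable | None = None,
                 model_params: dict | None = None, tokenizer=None, seed: int = 0):
        if family not in CONVENTIONAL_FAMILIES + DEEP_FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if family in DEEP_FAMILIES:
            use_text = True  # deep families always consume the note
        self.family = family
        self.use_text = use_text
        self.embedding_table = embedding_table
        self.model_params = dict(model_params or {})
        self.tokenizer = tokenizer
        self.seed = seed

    def _design(self, cohort: CohortTable) -> np.ndarray:
        return self.prep_.transform(cohort).to_numpy(dtype=np.float32)

    def fit(self, cohort_dev: CohortTable) -> "RiskPipeline":
        dev = add_missing_indicators(cohort_dev)
        self.prep_ = EMRPreprocessor().fit(dev)
        X = self.prep_.transform(dev).to_numpy(dtype=np.float32)
        y = cohort_dev.labels
        notes = cohort_dev.notes_tokens(self.tokenizer)
        if self.family in CONVENTIONAL_FAMILIES:
            if self.use_text:
                if self.embedding_table is None:
                    raise ValueError("use_text requires an embedding table")
                X = np.hstack([X, pooled_text_matrix(notes, self.embedding_table)])
            self.model_ = ConventionalRiskModel(
                self.family, self.use_text, seed=self.seed,
                **self.model_params).fit(X, y)
        else:
            self.model_ = train_deep(
                X, notes, y, family=self.family,
                embedding_table=self.embedding_table, seed=self.seed,
                **self.model_params)
        self.n_struct_ = X.shape[1]
        return self

    def score(self, cohort: CohortTable) -> np.ndarray:
        X = self._design(cohort)
        notes = cohort.notes_tokens(self.tokenizer)
        if self.family in CONVENTIONAL_FAMILIES:
            if self.use_text:
                X = np.hstack([X, pooled_text_matrix(notes, self.embedding_table)])
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict_proba(X, notes)[:, 1]

    # -- serialization ------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "family": self.family,
            "use_text": self.use_text,
            "seed": self.seed,
            "model_params": {k: v for k, v in self.model_params.items()
                             if not isinstance(v, EmbeddingTable)},
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2, default=str),
                                       encoding="utf-8")
        self.prep_.stats_.to_json(out / "preprocess_stats.json")
        if self.family in CONVENTIONAL_FAMILIES:
            with (out / "model.pkl").open("wb") as fh:
                pickle.dump(self.model_, fh)
        else:
            m = self.model_
            np.savez(out / "weights.npz", **m.net_.params)
            (out / "deep.json").write_text(json.dumps({
                "vocab": list(m.vocab_), "n_pad": m.n_pad_, "d": m.d_,
                "params": {k: v for k, v in m.get_params().items()
                           if k != "embedding_table"},
            }, default=lambda o: list(o) if isinstance(o, tuple) else str(o)),
                encoding="utf-8")
        if self.embedding_table is not None:
            self.embedding_table.save(out / "embeddings.txt")
        return out

    @classmethod
    def load(cls, out_dir: str | Path, schema: FeatureSchema) -> "RiskPipeline":
        out = Path(out_dir)
        meta = json.loads((out / "meta.json").read_text(encoding="utf-8"))
        table = None
        if (out / "embeddings.txt").exists():
            table = EmbeddingTable.load(out / "embeddings.txt")
        pipe = cls(meta["family"], meta["use_text"], embedding_table=table,
                   model_params=meta["model_params"], seed=meta["seed"])
        pipe.prep_ = EMRPreprocessor()
        pipe.prep_.stats_ = PreprocessStats.from_json(out / "preprocess_stats.json")
        pipe.prep_.feature_names_out_ = pipe.prep_._column_names(schema)
        if meta["family"] in CONVENTIONAL_FAMILIES:
            with (out / "model.pkl").open("rb") as fh:
                pipe.model_ = pickle.load(fh)
        else:
            deep = json.loads((out / "deep.json").read_text(encoding="utf-8"))
            params = deep["params"]
            for key in ("windows",):
                if key in params:
                    params[key] = tuple(params[key])
            klass = TextCNNClassifier if meta["family"] == "cnn" \
                else AttentiveBiLSTMClassifier
            model = klass(embedding_table=table, **params)
            model.vocab_ = {w: i for i, w in enumerate(deep["vocab"])}
            model.n_pad_ = deep["n_pad"]
            model.d_ = deep["d"]
            weights = dict(np.load(out / "weights.npz"))
            V = len(model.vocab_)
            n_struct = (weights["W1"].shape[0] - len(model.windows) * model.channels
                        if meta["family"] == "cnn"
                        else weights["Wd"].shape[0] - model.d2 * 2 * model.m)
            net = model._build_net_loaded(weights, n_struct)
            model.net_ = net
            pipe.model_ = model
        return pipe
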