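"""Risk predictors: conventional tabular families and deep fusion networks.

All models produce SSI risk scores in (0, 1) and are trained with
class-weighted loss (positive weight = N_neg / N_pos) to handle the rare
outcome.  Conventional families (L1-penalised logistic regression, random
forest, gradient-boosted trees) consume the structured design matrix,
optionally concatenated with a max-pooled text-embedding vector.  The two
deep families — a convolutional text network and a Bi-LSTM self-attention
network — consume the padded token sequence end to end, fine-tuning the
embedding layer jointly with the network under AdamW.

Estimators follow the sklearn protocol: hyperparameters in ``__init__``,
``fit``/``predict_proba``, fitted attributes with trailing underscores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
import xgboost as xgb

from . import _nn
from .embeddings import EmbeddingTable, compute_padding_length
from .validation import auroc

CONVENTIONAL_FAMILIES = ("l1_logistic", "random_forest", "gbdt")
DEEP_FAMILIES = ("cnn", "self_attention")

# tuned operating points (with_text -> hyperparameters)
_CONVENTIONAL_DEFAULTS = {
    "l1_logistic": {
        True: {"l1_penalty": 0.01},
        False: {"l1_penalty": 0.003},
    },
    "random_forest": {
        True: {"n_estimators": 300, "max_depth": 18, "max_features": 0.6},
        False: {"n_estimators": 1000, "max_depth": 4, "max_features": 0.6},
    },
    "gbdt": {
        True: {"learning_rate": 0.01, "max_depth": 24, "subsample": 0.6,
               "colsample_bytree": 0.65, "gamma": 0.3, "n_estimators": 61},
        False: {"learning_rate": 0.003, "max_depth": 4, "subsample": 0.65,
                "colsample_bytree": 0.8, "gamma": 0.0, "n_estimators": 132},
    },
}


# ---------------------------------------------------------------------------
# text pooling and feature assembly
# ---------------------------------------------------------------------------

def max_pool(matrix: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Column-wise maximum over token rows (the pooled text vector).

    With a boolean *mask*, only rows where mask is true participate
    (used to exclude zero-padding); without one, all rows do.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("embedding matrix must be non-empty and 2-D")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return np.zeros(matrix.shape[1], dtype=matrix.dtype)
        matrix = matrix[mask]
    return matrix.max(axis=0)


def assemble_features(design_row: np.ndarray,
                      pooled: np.ndarray | None = None) -> np.ndarray:
    """Concatenate structured block then (optionally) pooled text block."""
    design_row = np.asarray(design_row, dtype=float).ravel()
    if pooled is None:
        return design_row
    return np.concatenate([design_row, np.asarray(pooled, dtype=float).ravel()])


def pooled_text_matrix(notes_tokens: list[list[str]],
                       table: EmbeddingTable) -> np.ndarray:
    """Max-pooled d-vector per note; empty notes give the zero vector."""
    out = np.zeros((len(notes_tokens), table.d), dtype=np.float32)
    for i, toks in enumerate(notes_tokens):
        if toks:
            out[i] = max_pool(np.stack([table.vector(t) for t in toks]))
    return out


def weighted_loss(probs, labels, pos_weight) -> float:
    """Mean class-weighted cross-entropy; probabilities clamped at 1e-7."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if ((probs <= 0) | (probs >= 1)).any():
        warnings.warn("probabilities at 0/1 clamped to [1e-7, 1-1e-7]")
    p = np.clip(probs, 1e-7, 1 - 1e-7)
    return float(-(pos_weight * labels * np.log(p)
                   + (1 - labels) * np.log(1 - p)).mean())


def positive_weight(y) -> float:
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_neg / n_pos


# ---------------------------------------------------------------------------
# conventional families
# ---------------------------------------------------------------------------

class ConventionalRiskModel:
    """L1 logistic / random forest / GBDT with class weighting.

    ``use_text`` only selects the tuned hyperparameter defaults — the
    caller is responsible for concatenating pooled text features into X
    (see :func:`assemble_features`).  The L1 penalty is the inverse of
    sklearn's ``C``.
    """

    def __init__(self, family: str = "l1_logistic", use_text: bool = False,
                 seed: int = 0, **hyper):
        if family not in CONVENTIONAL_FAMILIES:
            raise ValueError(f"unknown conventional family {family!r}")
        self.family = family
        self.use_text = use_text
        self.seed = seed
        self.hyper = hyper

    def get_params(self, deep=True):
        return {"family": self.family, "use_text": self.use_text,
                "seed": self.seed, **self.hyper}

    def set_params(self, **params):
        for k in ("family", "use_text", "seed"):
            if k in params:
                setattr(self, k, params.pop(k))
        self.hyper.update(params)
        return self

    def _resolved(self) -> dict:
        out = dict(_CONVENTIONAL_DEFAULTS[self.family][bool(self.use_text)])
        out.update(self.hyper)
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class labels")
        w_pos = positive_weight(y)
        hp = self._resolved()
        if self.family == "l1_logistic":
            self.estimator_ = LogisticRegression(
                l1_ratio=1.0, C=1.0 / hp["l1_penalty"], solver="liblinear",
                class_weight={0: 1.0, 1: w_pos},
                max_iter=hp.get("max_iter", 30), tol=1e-4,
                random_state=self.seed)
        elif self.family == "random_forest":
            self.estimator_ = RandomForestClassifier(
                n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
                max_features=hp["max_features"],
                class_weight={0: 1.0, 1: w_pos}, random_state=self.seed,
                n_jobs=1)
        else:
            self.estimator_ = xgb.XGBClassifier(
                learning_rate=hp["learning_rate"], max_depth=hp["max_depth"],
                subsample=hp["subsample"],
                colsample_bytree=hp["colsample_bytree"], gamma=hp["gamma"],
                n_estimators=hp["n_estimators"], scale_pos_weight=w_pos,
                random_state=self.seed, n_jobs=1, tree_method="hist",
                eval_metric="logloss")
        self.estimator_.fit(X, y)
        self.pos_weight_ = w_pos
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        proba = self.estimator_.predict_proba(np.asarray(X, dtype=float))
        return np.clip(proba, 1e-7, 1 - 1e-7)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def coef_(self):
        return self.estimator_.coef_


def train_conventional(features, labels, family="l1_logistic", use_text=False,
                       seed=0, **hyper) -> ConventionalRiskModel:
    """Fit a conventional family on an assembled feature matrix."""
    return ConventionalRiskModel(family, use_text, seed, **hyper).fit(features, labels)


# ---------------------------------------------------------------------------
# deep fusion classifiers
# ---------------------------------------------------------------------------

class _DeepTextClassifier:
    """Shared machinery: vocabulary, padding, AdamW loop, early stopping."""

    _net_cls: type

    def __init__(self, embedding_table=None, d=128, n_pad=None, lr=1e-4,
                 weight_decay=0.0, epochs=10, batch_size=64,
                 early_stopping=False, patience=3, validation_fraction=0.1,
                 dense_units=128, finetune_embeddings=True, seed=0):
        self.embedding_table = embedding_table
        self.d = d
        self.n_pad = n_pad
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stopping = early_stopping
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.dense_units = dense_units
        self.finetune_embeddings = finetune_embeddings
        self.seed = seed

    # sklearn-style param plumbing
    def get_params(self, deep=True):
        import inspect
        keys = [k for k in inspect.signature(type(self).__init__).parameters
                if k != "self"]
        return {k: getattr(self, k) for k in keys}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _min_len(self) -> int:
        return 1

    def _build_net(self, emb_init, n_struct, seed):  # pragma: no cover - abstract
        raise NotImplementedError

    def _encode(self, notes, n_pad):
        """Left-padded id matrix + true (truncated) lengths."""
        V = len(self.vocab_)
        ids = np.full((len(notes), n_pad), V, dtype=np.int64)  # pad id = V
        lengths = np.zeros(len(notes), dtype=np.int64)
        for i, toks in enumerate(notes):
            row = [self.vocab_[t] for t in toks if t in self.vocab_]
            row = row[-n_pad:]
            if row:
                ids[i, n_pad - len(row):] = row
                lengths[i] = len(row)
        return ids, lengths

    def fit(self, X_struct, notes, y):
        X_struct = np.asarray(X_struct, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class labels")
        rng = np.random.default_rng(self.seed)

        vocab = sorted({t for toks in notes for t in toks})
        self.vocab_ = {w: i for i, w in enumerate(vocab)}
        V = len(vocab)
        if self.embedding_table is not None:
            d = self.embedding_table.d
            E = np.zeros((V + 1, d), dtype=np.float32)
            for w, i in self.vocab_.items():
                E[i] = self.embedding_table.vector(w)
        else:
            d = self.d
            E = rng.normal(0, 0.1, size=(V + 1, d)).astype(np.float32)
            E[V] = 0.0
        self.d_ = d

        lengths_dev = [max(len(t), 1) for t in notes]
        self.n_pad_ = self.n_pad or max(compute_padding_length(lengths_dev),
                                        self._min_len())
        self.n_pad_ = max(self.n_pad_, self._min_len())

        net = self._build_net(E, X_struct.shape[1], int(rng.integers(2**31)))
        self.net_ = net
        trainable = {k: v for k, v in net.params.items()
                     if self.finetune_embeddings or k != "E"}
        opt = _nn.AdamW(trainable, lr=self.lr, weight_decay=self.weight_decay,
                        no_decay=net.no_decay)

        ids_all, len_all = self._encode(notes, self.n_pad_)
        w_pos = positive_weight(y)
        self.pos_weight_ = w_pos

        idx = np.arange(len(y))
        if self.early_stopping:
            rng.shuffle(idx)
            n_val = max(2, int(self.validation_fraction * len(y)))
            # keep both classes in validation
            pos = idx[y[idx] == 1]
            neg = idx[y[idx] == 0]
            n_val_pos = max(1, int(round(n_val * len(pos) / len(y))))
            val_idx = np.concatenate([pos[:n_val_pos], neg[:n_val - n_val_pos]])
            train_idx = np.setdiff1d(idx, val_idx)
        else:
            train_idx, val_idx = idx, None

        self.loss_history_ = []
        best_auc, best_params, bad = -np.inf, None, 0
        for epoch in range(self.epochs):
            order = train_idx.copy()
            rng.shuffle(order)
            # bucket by length inside shuffled chunks: cheap batches, random SGD
            chunk = self.batch_size * 8
            order = np.concatenate([
                order[s:s + chunk][np.argsort(len_all[order[s:s + chunk]], kind="stable")]
                for s in range(0, len(order), chunk)])
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, len(order), self.batch_size):
                b = order[s:s + self.batch_size]
                if len(b) < 2:
                    continue
                trim = max(int(len_all[b].max()), self._min_len())
                ids_b = ids_all[b][:, self.n_pad_ - trim:]
                logit, cache, *_ = _unpack_forward(
                    net.forward(ids_b, len_all[b], X_struct[b], train=True, rng=rng))
                loss, dlogit = _nn.weighted_bce_grad(logit, y[b], w_pos)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {epoch}")
                grads = net.backward(cache, dlogit.astype(np.float32))
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            self.loss_history_.append(epoch_loss / max(n_batches, 1))
            if self.early_stopping:
                val_scores = self._score_ids(ids_all[val_idx], len_all[val_idx],
                                             X_struct[val_idx])
                auc = auroc(val_scores, y[val_idx])
                if auc > best_auc + 1e-6:
                    best_auc, bad = auc, 0
                    best_params = {k: v.copy() for k, v in net.params.items()}
                else:
                    bad += 1
                    if bad >= self.patience:
                        break
        if self.early_stopping and best_params is not None:
            net.params.update(best_params)
            self.best_val_auroc_ = best_auc
        return self

    def _build_net_loaded(self, weights: dict, n_struct: int):
        """Reconstruct the network from serialized weight arrays."""
        net = self._build_net(weights["E"], n_struct, 0)
        for k in net.params:
            net.params[k] = np.asarray(weights[k])
        return net

    def _score_ids(self, ids, lengths, X_struct, batch=512):
        out = np.empty(len(ids), dtype=float)
        for s in range(0, len(ids), batch):
            b = slice(s, s + batch)
            trim = max(int(lengths[b].max()) if len(ids[b]) else 1, self._min_len())
            ids_b = ids[b][:, ids.shape[1] - trim:]
            logit, *_ = _unpack_forward(
                self.net_.forward(ids_b, lengths[b], X_struct[b], train=False))
            out[b] = _nn.sigmoid(logit)
        return out

    def predict_proba(self, X_struct, notes):
        X_struct = np.asarray(X_struct, dtype=np.float32)
        ids, lengths = self._encode(notes, self.n_pad_)
        p1 = self._score_ids(ids, lengths, X_struct)
        return np.column_stack([1 - p1, p1])

    def decision_scores(self, X_struct, notes):
        return self.predict_proba(X_struct, notes)[:, 1]


def _unpack_forward(res):
    # nets return (logit, cache) or (logit, cache, attention)
    return res if len(res) == 3 else (*res, None)


class TextCNNClassifier(_DeepTextClassifier):
    """Convolutional text network fused with structured features.

    Defaults follow the tuned operating point: filter windows 3/4/5 with
    256 channels each, dense layer of 128 units, dropout 0/0.35/0.5
    (embedding / post-pooling / post-dense), AdamW with learning rate
    1e-4 and decoupled weight decay 3, 18 epochs.
    """

    def __init__(self, embedding_table=None, d=128, n_pad=None, lr=1e-4,
                 weight_decay=3.0, epochs=18, batch_size=64,
                 early_stopping=False, patience=3, validation_fraction=0.1,
                 dense_units=128, finetune_embeddings=True, seed=0,
                 windows=(3, 4, 5), channels=256,
                 dropout_emb=0.0, dropout_conv=0.35, dropout_dense=0.5):
        super().__init__(embedding_table, d, n_pad, lr, weight_decay, epochs,
                         batch_size, early_stopping, patience,
                         validation_fraction, dense_units,
                         finetune_embeddings, seed)
        self.windows = tuple(windows)
        self.channels = channels
        self.dropout_emb = dropout_emb
        self.dropout_conv = dropout_conv
        self.dropout_dense = dropout_dense

    def _min_len(self) -> int:
        return max(self.windows)

    def _build_net(self, emb_init, n_struct, seed):
        if max(self.windows) > self.n_pad_:
            raise ValueError("filter window exceeds padding length")
        return _nn.CNNNet(emb_init, n_struct, windows=self.windows,
                          channels=self.channels, dense_units=self.dense_units,
                          dropout_emb=self.dropout_emb,
                          dropout_conv=self.dropout_conv,
                          dropout_dense=self.dropout_dense, seed=seed)


class AttentiveBiLSTMClassifier(_DeepTextClassifier):
    """Bi-LSTM self-attention network fused with structured features.

    Defaults follow the tuned operating point: hidden size 256 per
    direction, attention layers 256/64, dense layer of 128 units, dropout
    0.5/0.45/0 (embedding / post-LSTM / post-dense), AdamW with learning
    rate 1e-4 and decoupled weight decay 0.03, 19 epochs.
    """

    def __init__(self, embedding_table=None, d=128, n_pad=None, lr=1e-4,
                 weight_decay=0.03, epochs=19, batch_size=64,
                 early_stopping=False, patience=3, validation_fraction=0.1,
                 dense_units=128, finetune_embeddings=True, seed=0,
                 m=256, d1=256, d2=64,
                 dropout_emb=0.5, dropout_lstm=0.45, dropout_dense=0.0):
        super().__init__(embedding_table, d, n_pad, lr, weight_decay, epochs,
                         batch_size, early_stopping, patience,
                         validation_fraction, dense_units,
                         finetune_embeddings, seed)
        self.m = m
        self.d1 = d1
        self.d2 = d2
        self.dropout_emb = dropout_emb
        self.dropout_lstm = dropout_lstm
        self.dropout_dense = dropout_dense

    def _build_net(self, emb_init, n_struct, seed):
        return _nn.AttnNet(emb_init, n_struct, m=self.m, d1=self.d1,
                           d2=self.d2, dense_units=self.dense_units,
                           dropout_emb=self.dropout_emb,
                           dropout_lstm=self.dropout_lstm,
                           dropout_dense=self.dropout_dense, seed=seed)

    def attention(self, X_struct, notes):
        """Attention matrices (one d2 x n_pad row-stochastic matrix per note)."""
        X_struct = np.asarray(X_struct, dtype=np.float32)
        ids, lengths = self._encode(notes, self.n_pad_)
        _, _, A = self.net_.forward(ids, lengths, X_struct, train=False)
        return A


def train_deep(X_struct, notes, y, family="cnn", **params):
    """Fit a deep fusion family on structured features + tokenised notes."""
    if family == "cnn":
        model = TextCNNClassifier(**params)
    elif family == "self_attention":
        model = AttentiveBiLSTMClassifier(**params)
    else:
        raise ValueError(f"unknown deep family {family!r}")
    return model.fit(X_struct, notes, y)


# ---------------------------------------------------------------------------
# functional forward surfaces (used by equivalence tests and explanations)
# ---------------------------------------------------------------------------

def _emb_matrix_net(padded: np.ndarray, net_factory):
    """Run a net on an explicit padded embedding matrix via an identity vocab."""
    padded = np.asarray(padded, dtype=np.float32)
    n, d = padded.shape
    E = np.vstack([padded, np.zeros((1, d), dtype=np.float32)])
    ids = np.arange(n, dtype=np.int64)[None, :]
    return E, ids


def infer_length(padded: np.ndarray) -> int:
    """Number of trailing non-pad rows (leading all-zero rows are padding)."""
    nz = np.flatnonzero(np.abs(padded).sum(axis=1) > 0)
    return int(padded.shape[0] - nz[0]) if len(nz) else 0


def cnn_forward(padded, structured, net: "_nn.CNNNet", length=None):
    """Probability and per-window GELU conv maps for one padded note.

    ``net`` carries the convolutional parameters; ``length`` defaults to
    the number of rows after the leading zero padding.  Dropout is off.
    """
    padded = np.asarray(padded, dtype=np.float32)
    if length is None:
        length = infer_length(padded)
    E, ids = _emb_matrix_net(padded, None)
    net.params["E"] = E
    net.pad_id = E.shape[0] - 1
    logit, cache = net.forward(ids, np.array([length]),
                               np.asarray(structured, dtype=np.float32)[None, :],
                               train=False)
    conv_maps = [_nn.gelu(pre[0]) for (_, pre, _, _) in cache[3]]
    return float(_nn.sigmoid(logit)[0]), conv_maps


def attention_forward(padded, structured, net: "_nn.AttnNet", length=None):
    """Probability and attention matrix A (d2 x n, rows sum to 1) for one note."""
    padded = np.asarray(padded, dtype=np.float32)
    if length is None:
        length = infer_length(padded)
    E, ids = _emb_matrix_net(padded, None)
    net.params["E"] = E
    net.pad_id = E.shape[0] - 1
    logit, cache, A = net.forward(ids, np.array([length]),
                                  np.asarray(structured, dtype=np.float32)[None, :],
                                  train=False)
    return float(_nn.sigmoid(logit)[0]), A[0]


# ---------------------------------------------------------------------------
# random hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class SearchTrial:
    config: dict
    fold_aurocs: list = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_aurocs))


def random_search(space: dict, factory, X, y, folds: int = 5,
                  trials: int = 10, seed: int = 0):
    """Random search over *space* by stratified K-fold mean AUROC.

    ``space`` maps a hyperparameter to a list of candidates or a callable
    ``rng -> value``; ``factory(**config)`` must return an estimator with
    ``fit``/``predict_proba``.  Returns (best_config, trial_log).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    log: list[SearchTrial] = []
    for _ in range(trials):
        config = {}
        for name, cand in space.items():
            config[name] = cand(rng) if callable(cand) else \
                cand[int(rng.integers(len(cand)))]
        trial = SearchTrial(config=config)
        for tr, va in skf.split(X, y):
            est = factory(**config)
            est.fit(X[tr], y[tr])
            trial.fold_aurocs.append(auroc(est.predict_proba(X[va])[:, 1], y[va]))
        log.append(trial)
    best = max(log, key=lambda t: t.mean_auroc)
    return best.config, log
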