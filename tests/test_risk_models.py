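"""Pooling, feature assembly, conventional families, deep training, search."""

import numpy as np
import pytest

from ssirisk.risk_models import (
    AttentiveBiLSTMClassifier,
    ConventionalRiskModel,
    TextCNNClassifier,
    assemble_features,
    max_pool,
    pooled_text_matrix,
    random_search,
    train_conventional,
)
from ssirisk.validation import auroc

from _oracles import max_pool_loops


class TestMaxPool:
    def test_worked_example(self):
        assert np.array_equal(max_pool([[1, 5], [3, 2]]), [3, 5])

    def test_single_row_identity(self):
        assert np.array_equal(max_pool([[4.0, -1.0, 2.0]]), [4.0, -1.0, 2.0])

    def test_matches_loop_oracle(self, rng):
        M = rng.normal(0, 1, (50, 8))
        assert np.allclose(max_pool(M), max_pool_loops(M))

    def test_mask_excludes_padding_rows(self):
        M = np.array([[0.0, 9.0], [1.0, 2.0]])
        out = max_pool(M, mask=[False, True])
        assert np.array_equal(out, [1.0, 2.0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((0, 4)))


class TestAssembleFeatures:
    def test_concatenation_order_and_length(self, rng):
        row = rng.normal(0, 1, 47)
        pooled = rng.normal(0, 1, 128)
        vec = assemble_features(row, pooled)
        assert vec.shape == (175,)
        assert np.array_equal(vec[:47], row)
        assert np.array_equal(vec[47:], pooled)

    def test_without_pooled_block(self, rng):
        row = rng.normal(0, 1, 10)
        assert np.array_equal(assemble_features(row), row)

    def test_deterministic(self, rng):
        row, pooled = rng.normal(0, 1, 5), rng.normal(0, 1, 4)
        assert np.array_equal(assemble_features(row, pooled),
                              assemble_features(row, pooled))


class TestConventional:
    def test_separable_data_reaches_perfect_training_auroc(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (50, 2)), rng.normal(2, 0.3, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        for family in ("l1_logistic", "random_forest", "gbdt"):
            model = train_conventional(X, y, family=family, seed=0)
            assert auroc(model.predict_proba(X)[:, 1], y) == 1.0

    def test_permuted_labels_give_chance_auroc(self, rng):
        n = 5000
        X = rng.normal(0, 1, (n, 10))
        y = rng.permutation(np.array([1] * (n // 2) + [0] * (n // 2)))
        half = n // 2
        model = train_conventional(X[:half], y[:half], family="l1_logistic", seed=1)
        a = auroc(model.predict_proba(X[half:])[:, 1], y[half:])
        assert 0.45 <= a <= 0.55

    def test_l1_concentrates_on_planted_signals(self, rng):
        n, p = 3000, 20
        X = rng.normal(0, 1, (n, p))
        logit = 1.5 * X[:, 2] - 1.2 * X[:, 7] + 1.0 * X[:, 13]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = train_conventional(X, y, family="l1_logistic",
                                   l1_penalty=0.05, seed=2)
        top3 = np.argsort(np.abs(model.coef_.ravel()))[-3:]
        assert len(set(top3) & {2, 7, 13}) >= 2

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 3))
        with pytest.raises(ValueError):
            train_conventional(X, np.zeros(20, dtype=int))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ConventionalRiskModel("svm")

    def test_sklearn_param_protocol(self):
        model = ConventionalRiskModel("gbdt", use_text=True, seed=3)
        params = model.get_params()
        assert params["family"] == "gbdt" and params["use_text"]
        model.set_params(seed=9)
        assert model.seed == 9


def _toy_text_problem(rng, n=600, key="danger"):
    """Short notes where one keyword fully determines the label."""
    vocab = [f"w{i}" for i in range(30)]
    notes, y = [], []
    for i in range(n):
        toks = list(rng.choice(vocab, size=10))
        label = int(rng.random() < 0.5)
        if label:
            toks[int(rng.integers(10))] = key
        notes.append(toks)
        y.append(label)
    X = rng.normal(0, 1, (n, 3)).astype(np.float32)
    return X, notes, np.array(y)


class TestDeepClassifiers:
    @pytest.mark.parametrize("cls,extra", [
        (TextCNNClassifier, dict(windows=(2, 3), channels=4)),
        (AttentiveBiLSTMClassifier, dict(m=4, d1=8, d2=2)),
    ])
    def test_loss_decreases_on_learnable_data(self, rng, cls, extra):
        X, notes, y = _toy_text_problem(rng)
        model = cls(d=8, dense_units=8, epochs=3, lr=3e-3, batch_size=64,
                    seed=0, **extra)
        model.fit(X, notes, y)
        assert model.loss_history_[0] > model.loss_history_[1] > model.loss_history_[2]

    def test_same_seed_identical_weights(self, rng):
        X, notes, y = _toy_text_problem(rng, n=200)
        runs = []
        for _ in range(2):
            m = TextCNNClassifier(d=8, windows=(2,), channels=3, dense_units=4,
                                  epochs=2, batch_size=32, seed=5)
            m.fit(X, notes, y)
            runs.append({k: v.copy() for k, v in m.net_.params.items()})
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k]), k

    def test_keyword_signal_learned(self, rng):
        X, notes, y = _toy_text_problem(rng, n=800)
        model = TextCNNClassifier(d=8, windows=(2, 3), channels=4,
                                  dense_units=8, epochs=12, lr=1e-2,
                                  dropout_conv=0, dropout_dense=0,
                                  batch_size=64, seed=1)
        model.fit(X[:600], notes[:600], y[:600])
        a = auroc(model.predict_proba(X[600:], notes[600:])[:, 1], y[600:])
        assert a > 0.9

    def test_single_class_rejected(self, rng):
        X, notes, _ = _toy_text_problem(rng, n=50)
        with pytest.raises(ValueError):
            TextCNNClassifier(epochs=1).fit(X, notes, np.zeros(50, dtype=int))

    def test_embedding_table_initialization_used(self, tiny_table, rng):
        notes = [["alpha", "beta"], ["gamma", "delta"]] * 20
        X = rng.normal(0, 1, (40, 2)).astype(np.float32)
        y = np.array([0, 1] * 20)
        m = TextCNNClassifier(embedding_table=tiny_table, windows=(2,),
                              channels=2, dense_units=4, epochs=0, seed=0)
        m.fit(X, notes, y)
        i = m.vocab_["alpha"]
        assert np.allclose(m.net_.params["E"][i], tiny_table.vector("alpha"),
                           atol=1e-6)


class TestPooledTextMatrix:
    def test_empty_note_gives_zero_row(self, tiny_table):
        out = pooled_text_matrix([[], ["alpha"]], tiny_table)
        assert np.allclose(out[0], 0.0)
        assert np.allclose(out[1], tiny_table.vector("alpha"))


class _RiggedEstimator:
    """predict_proba quality depends on the 'quality' hyperparameter."""

    def __init__(self, quality=0.0, seed=0):
        self.quality = quality
        self.seed = seed

    def fit(self, X, y):
        self.y_mean_ = y.mean()
        return self

    def predict_proba(self, X):
        rng = np.random.default_rng(self.seed)
        signal = X[:, 0]
        noise = rng.normal(0, 1, len(X))
        s = self.quality * signal + (1 - self.quality) * noise
        p = 1 / (1 + np.exp(-s))
        return np.column_stack([1 - p, p])


class TestRandomSearch:
    @pytest.fixture()
    def surface(self, rng):
        X = rng.normal(0, 1, (400, 3))
        y = (rng.random(400) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(int)
        return X, y

    def test_best_config_returned_when_sampled(self, surface):
        X, y = surface
        space = {"quality": [0.0, 0.2, 1.0]}
        best, log = random_search(space, _RiggedEstimator, X, y,
                                  folds=3, trials=12, seed=0)
        assert best["quality"] == 1.0
        assert len(log) == 12

    def test_single_trial_returned(self, surface):
        X, y = surface
        best, log = random_search({"quality": [0.7]}, _RiggedEstimator, X, y,
                                  folds=3, trials=1, seed=1)
        assert best == {"quality": 0.7}

    def test_zero_trials_rejected(self, surface):
        X, y = surface
        with pytest.raises(ValueError):
            random_search({"quality": [1]}, _RiggedEstimator, X, y, trials=0)

    def test_stratified_folds_preserve_class_ratio(self, rng):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([1] * 40 + [0] * 360)
        X = rng.normal(0, 1, (400, 2))
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, va in skf.split(X, y):
            assert abs(y[va].sum() - 8) <= 1
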