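"""AUROC, bootstrap mechanics, model comparison and operating points."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssirisk.emr_io import CohortTable, Feature, FeatureSchema
from ssirisk.validation import (
    BootstrapResult,
    auroc,
    bootstrap_validate,
    external_evaluate,
    paired_t_test,
    summarize_bootstrap,
    youden_cutoff,
)

from _oracles import auroc_allpairs, youden_exhaustive


class TestAUROC:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_tie_convention(self):
        assert auroc([0.5, 0.5], [1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_all_pairs_counting_exactly(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 30))
            # coarse grid forces ties
            scores = rng.integers(0, 6, n) / 5.0
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                auroc_allpairs(scores.tolist(), labels.tolist()), abs=1e-12)


class _StubPipeline:
    """Deterministic fit/score stub for bootstrap mechanics tests."""

    def __init__(self):
        self.seen = []

    def fit(self, cohort):
        self.seen.append(set(r.split("#")[0] for r in cohort.record_ids))
        return self

    def score(self, cohort):
        # deterministic pseudo-score from the record id
        import zlib
        return np.array([(zlib.crc32(r.encode()) % 997) / 997.0
                         for r in cohort.record_ids])


def _label_cohort(n, seed=0):
    rng = np.random.default_rng(seed)
    schema = FeatureSchema([Feature("x", "continuous")])
    df = pd.DataFrame({
        "record_id": [f"R{i}" for i in range(n)],
        "x": rng.normal(0, 1, n),
        "label": rng.integers(0, 2, n),
    })
    return CohortTable(df, schema)


class TestBootstrap:
    def test_oob_fraction_matches_e_inverse(self):
        cohort = _label_cohort(2000)
        res = bootstrap_validate(cohort, _StubPipeline, iterations=100, seed=1)
        assert abs(res.oob_fractions.mean() - np.exp(-1)) < 0.01

    def test_inbag_and_oob_partition_ids(self):
        cohort = _label_cohort(150)
        captured = {}

        class Recorder(_StubPipeline):
            def fit(self, c):
                captured["inbag"] = set(r.split("#")[0] for r in c.record_ids)
                return self

            def score(self, c):
                captured["oob"] = set(c.record_ids)
                return super().score(c)

        bootstrap_validate(cohort, Recorder, iterations=1, seed=2)
        union = captured["inbag"] | captured["oob"]
        assert union == set(cohort.record_ids)
        assert not (captured["inbag"] & captured["oob"]) - captured["inbag"]

    def test_same_seed_reproduces_auroc_vector(self):
        cohort = _label_cohort(300)
        a = bootstrap_validate(cohort, _StubPipeline, iterations=10, seed=3)
        b = bootstrap_validate(cohort, _StubPipeline, iterations=10, seed=3)
        assert np.array_equal(a.aurocs, b.aurocs)

    def test_auroc_range_invariant(self):
        with pytest.raises(ValueError):
            BootstrapResult(np.array([0.5, 1.2]), np.array([0.3, 0.3]), 0, 10)


class TestSummarize:
    def test_constant_vector(self):
        res = BootstrapResult(np.full(10, 0.8), np.full(10, 0.37), 0, 100)
        mean, (lo, hi) = summarize_bootstrap(res)
        assert (mean, lo, hi) == (0.8, 0.8, 0.8)

    def test_two_point_closed_form(self):
        res = BootstrapResult(np.array([0.7, 0.9]), np.array([0.4, 0.4]), 0, 10)
        mean, (lo, hi) = summarize_bootstrap(res)
        sd = np.std([0.7, 0.9], ddof=1)
        half = stats.t.ppf(0.975, 1) * sd / np.sqrt(2)
        assert mean == pytest.approx(0.8)
        assert lo == pytest.approx(0.8 - half)
        assert hi == pytest.approx(0.8 + half)

    def test_ci_shrinks_with_more_iterations(self, rng):
        a = rng.uniform(0.7, 0.9, 100)
        res_small = BootstrapResult(a[:10], np.full(10, .4), 0, 10)
        res_big = BootstrapResult(a, np.full(100, .4), 0, 10)
        _, (lo_s, hi_s) = summarize_bootstrap(res_small)
        _, (lo_b, hi_b) = summarize_bootstrap(res_big)
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_percentile_method(self, rng):
        a = rng.uniform(0.6, 0.9, 200)
        _, (lo, hi) = summarize_bootstrap(
            BootstrapResult(a, np.full(200, .4), 0, 10), method="percentile")
        assert lo == pytest.approx(np.quantile(a, 0.025))
        assert hi == pytest.approx(np.quantile(a, 0.975))

    def test_ci_coverage_for_known_process(self):
        """t-intervals over iid AUROC draws cover the true AUROC ~95%."""
        rng = np.random.default_rng(17)
        delta = 1.0
        true_auroc = stats.norm.cdf(delta / np.sqrt(2))
        covered = 0
        for _ in range(100):
            aurocs = []
            for _ in range(25):
                neg = rng.normal(0, 1, 100)
                pos = rng.normal(delta, 1, 100)
                scores = np.concatenate([neg, pos])
                labels = np.array([0] * 100 + [1] * 100)
                aurocs.append(auroc(scores, labels))
            res = BootstrapResult(np.array(aurocs), np.full(25, .4), 0, 200)
            _, (lo, hi) = summarize_bootstrap(res)
            covered += lo <= true_auroc <= hi
        assert covered >= 90


class TestPairedT:
    def test_closed_form_example(self):
        t, p = paired_t_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert p == pytest.approx(0.0742, abs=0.003)

    def test_identical_vectors_give_p_one(self):
        _, p = paired_t_test([0.8, 0.9], [0.8, 0.9])
        assert p == 1.0

    def test_constant_offset_gives_p_zero(self):
        _, p = paired_t_test([0.8, 0.9], [0.8 + 1e-6, 0.9 + 1e-6])
        assert p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])


class TestYouden:
    def test_worked_example(self):
        op = youden_cutoff([0.2, 0.3, 0.6, 0.9], [0, 1, 0, 1])
        assert op.threshold == 0.3
        assert op.sensitivity == 1.0
        assert op.specificity == 0.5

    def test_perfect_separation(self):
        op = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (op.sensitivity, op.specificity, op.j) == (1.0, 1.0, 1.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            n = 200
            scores = rng.integers(0, 50, n) / 49.0
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            op = youden_cutoff(scores, labels)
            t, sens, spec, j = youden_exhaustive(scores.tolist(), labels.tolist())
            assert (op.threshold, op.sensitivity, op.specificity) == (t, sens, spec)
            assert op.j == pytest.approx(j)


class TestExternal:
    def test_perfectly_separating_nnis_baseline(self):
        scores = [0.2, 0.4, 0.6, 0.9]
        labels = [0, 0, 1, 1]
        nnis = [0, 1, 2, 3]
        report = external_evaluate(scores, labels, nnis)
        assert report.nnis_auroc == 1.0

    def test_roc_points_monotone(self, rng):
        scores = rng.uniform(0, 1, 300)
        labels = rng.integers(0, 2, 300)
        labels[0], labels[1] = 0, 1
        roc = external_evaluate(scores, labels).roc_points
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()

    def test_empty_test_split_rejected(self):
        with pytest.raises(ValueError):
            external_evaluate([], [])
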