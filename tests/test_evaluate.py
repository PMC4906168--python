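import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_cindex

from isosurv import (
    SurvivalRecord,
    concordance_index,
    kaplan_meier,
    logrank_test,
    roc_from_pvalues,
    two_means_stratify,
)


def _records(times, events):
    return [SurvivalRecord(f"p{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


class TestRoc:
    def test_perfect_separation(self):
        p = [0.001, 0.002, 0.8, 0.9]
        roc = roc_from_pvalues(p, [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.tpr_at[0.05] == 1.0

    def test_hand_ranked_example(self):
        roc = roc_from_pvalues([0.01, 0.2, 0.3, 0.9], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=4000)
        y = rng.integers(0, 2, size=4000)
        roc = roc_from_pvalues(p, y)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        y = (rng.uniform(size=200) < 0.3).astype(int)
        a = roc_from_pvalues(p, y)
        b = roc_from_pvalues(p**3, y)  # strictly monotone in p
        assert a.auc == pytest.approx(b.auc)
        assert a.tpr_at[0.05] == b.tpr_at[0.05]

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_from_pvalues([0.1, 0.2], [1, 1])


class TestConcordance:
    def test_perfect_and_hand_example(self):
        recs = _records([1, 2, 3], [1, 1, 1])
        assert concordance_index([3, 2, 1], recs) == 1.0
        assert concordance_index([3, 1, 2], recs) == pytest.approx(2 / 3)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        recs = _records(rng.exponential(size=800),
                        rng.integers(0, 2, size=800))
        c = concordance_index(rng.uniform(size=800), recs)
        assert c == pytest.approx(0.5, abs=0.05)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        recs = _records(rng.exponential(size=120),
                        rng.integers(0, 2, size=120))
        assert concordance_index(scores, recs) + concordance_index(
            -scores, recs
        ) == pytest.approx(1.0)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(size=150)
        events = rng.integers(0, 2, size=150)
        events[0] = 1
        scores = rng.normal(size=150)
        recs = _records(times, events)
        mine = concordance_index(scores, recs)
        # lifelines scores predictions that increase with survival time
        ref = ll_cindex(times, -scores, events)
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], _records([1, 2], [0, 0]))


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = kaplan_meier(_records([1, 2, 3], [0, 0, 0]))
        assert km.at([0.5, 10.0]).tolist() == [1.0, 1.0]

    def test_product_limit_by_hand(self):
        km = kaplan_meier(_records([1, 2], [1, 1]))
        np.testing.assert_allclose(km.surv_prob, [0.5, 0.0])
        assert km.at(1.5) == 0.5

    def test_censoring_before_first_event(self):
        km = kaplan_meier(_records([1, 2], [0, 1]))
        assert km.at(1.5) == 1.0
        assert km.at(2.0) == 0.0  # only one at risk at t=2

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(size=100)
        events = rng.integers(0, 2, size=100)
        events[:2] = 1
        km = kaplan_meier(_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.surv_prob, ref, atol=1e-12)


class TestTwoMeans:
    def test_separated_clusters(self):
        labels = two_means_stratify([0.1, 0.1, 0.9, 0.9])
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_enumerated_split(self):
        # splits of sorted (0, .4, .5, 1): best SSE groups {0,.4,.5 | 1}
        labels = two_means_stratify([0.0, 0.4, 0.5, 1.0])
        np.testing.assert_array_equal(labels, [0, 0, 0, 1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(size=50)
        perm = rng.permutation(50)
        labels = two_means_stratify(x)
        labels_perm = two_means_stratify(x[perm])
        np.testing.assert_array_equal(labels[perm], labels_perm)

    def test_matches_exhaustive_sse_search(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=40)
            labels = two_means_stratify(x)
            sse = min(
                np.var(g0) * len(g0) + np.var(g1) * len(g1)
                for g0, g1 in [
                    (np.sort(x)[:k], np.sort(x)[k:]) for k in range(1, 40)
                ]
            )
            got = sum(
                np.var(x[labels == g]) * (labels == g).sum() for g in (0, 1)
            )
            assert got == pytest.approx(sse)
            assert x[labels == 1].mean() > x[labels == 0].mean()

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            two_means_stratify([0.5, 0.5, 0.5])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        recs = _records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        assert logrank_test([0, 0, 0, 1, 1, 1], recs) == pytest.approx(1.0)

    def test_strong_separation(self):
        rng = np.random.default_rng(8)
        t0 = rng.exponential(1.0, size=100)
        t1 = rng.exponential(5.0, size=100)
        recs = _records(np.concatenate([t0, t1]), np.ones(200))
        p = logrank_test(np.repeat([0, 1], 100), recs)
        assert p < 1e-4

    def test_matches_lifelines(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(size=80)
        events = rng.integers(0, 2, size=80)
        events[:2] = 1
        groups = rng.integers(0, 2, size=80)
        if len(np.unique(groups)) < 2:
            groups[0] = 1 - groups[0]
        recs = _records(times, events)
        mine = logrank_test(groups, recs)
        ref = ll_logrank(times[groups == 0], times[groups == 1],
                         events[groups == 0], events[groups == 1]).p_value
        assert mine == pytest.approx(ref, abs=1e-8)
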