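import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elmcc import (
    ExpressionMatrix,
    concordance,
    km_estimate,
    logrank_test,
    pairwise_sigclust,
    sigclust_pair,
    signature_score,
)
from elmcc.cluster_select import SubtypeAssignment
from elmcc.evaluate import SurvivalTable


def survival_table(records):
    rows = [{"sample_id": f"s{i}", "time": t, "event": e, "group": g}
            for i, (t, e, g) in enumerate(records)]
    return SurvivalTable(pd.DataFrame(rows))


class TestSigClust:
    def test_cluster_index_in_unit_interval(self):
        rng = np.random.default_rng(0)
        res = sigclust_pair(rng.normal(size=(30, 4)), nsim=30, seed=1)
        assert 0 < res.cluster_index <= 1
        assert 0 < res.p_value <= 1

    def test_separated_clouds_significant(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(50, 1, (20, 5))])
        res = sigclust_pair(X, nsim=100, seed=2)
        assert res.p_value <= 0.01

    def test_small_nsim_rejected(self):
        with pytest.raises(ValueError):
            sigclust_pair(np.zeros((10, 2)), nsim=10)

    def test_pair_count_combinatorics(self):
        rng = np.random.default_rng(3)
        n_per = 10
        for k, expected_pairs in [(2, 1), (4, 6)]:
            X = np.vstack([rng.normal(30 * c, 1, (n_per, 3)) for c in range(k)])
            ids = [f"s{i}" for i in range(k * n_per)]
            a = SubtypeAssignment(ids, np.repeat(np.arange(1, k + 1), n_per), k=k)
            results, _ = pairwise_sigclust(X, a, nsim=25, seed=4)
            assert len(results) == expected_pairs

    def test_null_pvalues_approximately_uniform(self):
        # single-Gaussian data: p-values should be uniform on (0, 1]
        pvals = []
        for i in range(150):
            rng = np.random.default_rng(1000 + i)
            X = rng.normal(size=(30, 5))
            pvals.append(sigclust_pair(X, nsim=50, seed=2000 + i).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLogrank:
    def test_identical_groups_null(self):
        t = survival_table([(1, 1, 1), (2, 1, 1), (1, 1, 2), (2, 1, 2)])
        res = logrank_test(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        # A: events at 1, 2; B: events at 3, 4.
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (7/6)^2 / (17/36) = 49/17
        t = survival_table([(1, 1, 1), (2, 1, 1), (3, 1, 2), (4, 1, 2)])
        res = logrank_test(t)
        assert res.chi2 == pytest.approx(49 / 17, rel=1e-10)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(49 / 17, 1), rel=1e-10)

    def test_degrees_of_freedom_four_groups(self):
        recs = [(t, 1, g) for g in range(1, 5) for t in (g, g + 4.5)]
        assert logrank_test(survival_table(recs)).df == 3

    def test_zero_events_rejected(self):
        t = survival_table([(1, 0, 1), (2, 0, 2)])
        with pytest.raises(ValueError):
            logrank_test(t)

    def test_agrees_with_permutation_reference(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=24).round(3) + 0.1
        events = rng.integers(0, 2, size=24)
        events[0] = 1
        groups = np.tile([1, 2], 12)
        t = survival_table(list(zip(times, events, groups)))
        obs = logrank_test(t).chi2
        nperm = 4000
        exceed = 0
        for _ in range(nperm):
            gp = rng.permutation(groups)
            tp = survival_table(list(zip(times, events, gp)))
            if logrank_test(tp).chi2 >= obs - 1e-12:
                exceed += 1
        p_perm = (1 + exceed) / (1 + nperm)
        p_asym = logrank_test(t).p
        # Monte-Carlo + chi-square approximation error at n = 24
        assert abs(p_perm - p_asym) < 0.06


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        t = survival_table([(1, 0, 1), (2, 0, 1), (3, 0, 1)])
        curve = km_estimate(t, 1)
        assert np.all(curve.survival == 1.0)

    def test_product_limit_by_hand(self):
        t = survival_table([(1, 1, 1), (2, 1, 1)])
        curve = km_estimate(t, 1)
        assert curve.evaluate(1.0) == pytest.approx(0.5)
        assert curve.evaluate(2.0) == pytest.approx(0.0)
        assert curve.evaluate(0.5) == pytest.approx(1.0)

    def test_flat_after_last_event_with_trailing_censoring(self):
        # one event among 3 at risk -> S = 2/3, unchanged by later censoring
        t = survival_table([(1, 1, 1), (2, 0, 1), (3, 0, 1)])
        curve = km_estimate(t, 1)
        assert curve.evaluate(1.5) == curve.evaluate(3.0) == pytest.approx(2 / 3)

    def test_non_increasing(self):
        rng = np.random.default_rng(9)
        recs = [(t, e, 1) for t, e in zip(rng.exponential(5, 30) + 0.01,
                                          rng.integers(0, 2, 30))]
        curve = km_estimate(survival_table(recs), 1)
        assert np.all(np.diff(curve.survival) <= 1e-12)


class TestConcordance:
    def _assignment(self, labels, k):
        return SubtypeAssignment([f"s{i}" for i in range(len(labels))],
                                 np.asarray(labels), k=k)

    def test_identical_labelings(self):
        a = self._assignment([1, 1, 2, 2, 3, 3], k=3)
        ari, _ = concordance(a, np.array([1, 1, 2, 2, 3, 3]))
        assert ari == 1.0

    def test_relabeling_invariance(self):
        a = self._assignment([1, 1, 2, 2, 3, 3], k=3)
        ari, _ = concordance(a, np.array([3, 3, 1, 1, 2, 2]))
        assert ari == 1.0

    def test_hypergeometric_closed_form(self):
        # class of 5 fully overlapping a reference of 5 in N = 20
        labels = np.r_[np.ones(5, int), np.full(15, 2)]
        ref = np.r_[np.ones(5, int), np.full(15, 2)]
        a = self._assignment(labels, k=2)
        _, pmat = concordance(a, ref)
        from math import comb
        assert pmat.loc[1, 1] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_random_labelings_ari_near_zero(self):
        rng = np.random.default_rng(13)
        aris = []
        for _ in range(150):
            x = rng.integers(1, 5, 200)
            y = rng.integers(1, 5, 200)
            x[:4] = y[:4] = [1, 2, 3, 4]
            ari, _ = concordance(self._assignment(x, 4), y)
            aris.append(ari)
        assert abs(np.mean(aris)) < 0.02

    def test_disjoint_sample_sets_rejected(self):
        a = self._assignment([1, 2], k=2)
        b = SubtypeAssignment(["x1", "x2"], np.array([1, 2]), k=2)
        with pytest.raises(ValueError):
            concordance(a, b)


class TestSignatureScore:
    def _matrix(self):
        return ExpressionMatrix(
            ["CDKN1A", "MDM2", "OTHER"], ["s1", "s2"],
            np.array([[2.0, 6.0], [4.0, 8.0], [100.0, 100.0]]),
        )

    def test_two_gene_mean(self):
        score = signature_score(self._matrix(), ["CDKN1A", "MDM2"])
        assert score["s1"] == pytest.approx(3.0)
        assert score["s2"] == pytest.approx(7.0)

    def test_single_gene_equals_row(self):
        score = signature_score(self._matrix(), ["MDM2"])
        np.testing.assert_allclose(score.to_numpy(), [4.0, 8.0])

    def test_absent_gene_warns_and_uses_present(self):
        with pytest.warns(UserWarning, match="TP53"):
            score = signature_score(self._matrix(), ["CDKN1A", "TP53"])
        np.testing.assert_allclose(score.to_numpy(), [2.0, 6.0])

    def test_all_absent_rejected(self):
        with pytest.raises(ValueError):
            signature_score(self._matrix(), ["NOPE"])
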