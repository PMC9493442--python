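import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macroindex.association import (
    ContingencyTable,
    consensus_significance,
    fisher_exact_rxc,
    fit_alteration_logistic,
    fit_m2_regression,
    spearman,
    vif_reduce,
    wilcoxon_rank_sum,
)


class TestVifReduce:
    def test_orthogonal_predictors_all_kept(self):
        n = 40
        X = pd.DataFrame({
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.repeat([1.0, -1.0], n // 2),
        })
        assert vif_reduce(X) == ["a", "b"]

    def test_duplicated_column_drops_exactly_one(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": rng.normal(size=30), "c": x})
        kept = vif_reduce(X)
        assert kept == ["a", "b"]  # 'c' dropped: later name among the collinear pair

    def test_vif_values_match_brute_force(self, rng):
        """Three predictors with induced correlation: VIF = 1/(1 - R^2)."""
        n = 200
        z = rng.normal(size=n)
        X = pd.DataFrame({
            "a": z + 0.3 * rng.normal(size=n),
            "b": z + 0.3 * rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        from macroindex.association import _vif_one

        arr = X.to_numpy()
        import statsmodels.api as sm

        for j, col in enumerate(X.columns):
            others = sm.add_constant(np.delete(arr, j, axis=1))
            r2 = sm.OLS(arr[:, j], others).fit().rsquared
            assert _vif_one(arr, j) == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_no_kept_predictor_exceeds_threshold(self, rng):
        n = 100
        z = rng.normal(size=n)
        X = pd.DataFrame({f"p{i}": z + 0.2 * rng.normal(size=n) for i in range(5)})
        from macroindex.association import _vif_one

        kept = vif_reduce(X, threshold=5.0)
        arr = X[kept].to_numpy()
        if len(kept) >= 2:
            assert all(_vif_one(arr, j) < 5.0 for j in range(len(kept)))


class TestM2Regression:
    def test_identity_response_recovered(self, rng):
        n = 200
        X = pd.DataFrame({"sig": rng.normal(size=n), "noise": rng.normal(size=n)})
        m2 = pd.Series(X["sig"].to_numpy() + 0.01 * rng.normal(size=n))
        rep = fit_m2_regression(m2, X, "a")
        assert rep.loc["sig", "beta"] == pytest.approx(1.0, abs=0.05)
        assert rep.loc["sig", "p"] < 1e-6

    def test_type_one_error_calibrated(self, rng):
        """Under the null, about 5% of coefficients are significant."""
        n_rep, n = 300, 50
        hits = 0
        for _ in range(n_rep):
            X = pd.DataFrame({"x": rng.normal(size=n)})
            m2 = pd.Series(rng.normal(size=n))
            hits += fit_m2_regression(m2, X).loc["x", "p"] < 0.05
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_needs_enough_samples(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="n > p"):
            fit_m2_regression(pd.Series(np.ones(4)), X)


class TestConsensusSignificance:
    def _report(self, beta, p, tag):
        return pd.DataFrame({"beta": [beta], "p": [p], "algorithm": tag},
                            index=["f"])

    def test_two_positive_one_ns_is_positive(self):
        reports = [self._report(1.0, 0.01, "a"), self._report(0.8, 0.02, "b"),
                   self._report(0.1, 0.5, "c")]
        assert consensus_significance(reports).verdicts["f"] == "positive"

    def test_conflicting_signs_is_none(self):
        reports = [self._report(1.0, 0.01, "a"), self._report(-0.8, 0.02, "b"),
                   self._report(0.1, 0.5, "c")]
        assert consensus_significance(reports).verdicts["f"] == "none"

    def test_two_negative_is_negative(self):
        reports = [self._report(-1.0, 0.01, "a"), self._report(-0.8, 0.04, "b"),
                   self._report(-0.1, 0.5, "c")]
        assert consensus_significance(reports).verdicts["f"] == "negative"

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match="two algorithms"):
            consensus_significance([self._report(1.0, 0.01, "a")])


class TestAlterationLogistic:
    def test_null_alteration_beta_near_zero(self, rng):
        n = 400
        m2 = pd.Series(rng.uniform(0, 0.6, size=n))
        betas = []
        for _ in range(10):
            alt = pd.DataFrame(rng.integers(0, 2, size=(1, n)), index=["f"],
                               columns=m2.index)
            rep = fit_alteration_logistic(alt, m2)
            betas.append(rep.loc["f", "beta"])
        assert abs(np.mean(betas)) < 0.15

    def test_separation_flagged(self):
        n = 40
        m2 = pd.Series(np.linspace(0, 1, n))
        alt = pd.DataFrame((m2 > m2.median()).astype(int).to_numpy()[None, :],
                           index=["sep"], columns=m2.index)
        rep = fit_alteration_logistic(alt, m2)
        assert not rep.loc["sep", "estimable"]

    def test_planted_slope_recovered(self, rng):
        """Log-odds slope 2.0 per sd recovered within +/- 0.5 at n=400."""
        n = 400
        m2 = pd.Series(rng.uniform(0, 0.6, size=n))
        z = (m2 - m2.mean()) / m2.std(ddof=0)
        p = 1 / (1 + np.exp(-(-0.2 + 2.0 * z)))
        alt = pd.DataFrame((rng.random(n) < p).astype(int).to_numpy()[None, :],
                           index=["planted"], columns=m2.index)
        rep = fit_alteration_logistic(alt, m2)
        assert rep.loc["planted", "beta"] == pytest.approx(2.0, abs=0.5)

    def test_sparse_class_flagged(self, rng):
        n = 30
        m2 = pd.Series(rng.uniform(size=n))
        alt = pd.DataFrame(np.r_[1, 1, np.zeros(n - 2)][None, :].astype(int),
                           index=["rare"], columns=m2.index)
        rep = fit_alteration_logistic(alt, m2)
        assert not rep.loc["rare", "estimable"]


class TestFisherExact:
    def test_published_who_grade_table(self):
        res = fisher_exact_rxc(np.array([[47, 93], [89, 64]]))
        assert res["p"] == pytest.approx(3.732e-05, rel=1e-3)

    def test_homogeneous_table_p_one(self):
        assert fisher_exact_rxc(np.array([[5, 5], [5, 5]]))["p"] == pytest.approx(1.0)

    def test_2x2_matches_scipy_over_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(1, 15, size=(2, 2))
            mine = fisher_exact_rxc(t)["p"]
            ref = stats.fisher_exact(t)[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_3x2_matches_monte_carlo_permutation(self, rng):
        """Small 3x2 table: exact p within 3 SE of a label-permutation MC."""
        t = np.array([[4, 2], [1, 5], [3, 3]])
        res = fisher_exact_rxc(t)
        # Monte-Carlo: permute category labels, compare table probabilities
        rows = np.repeat(np.arange(3), t.sum(axis=1))
        cols = np.repeat(np.arange(2), t.sum(axis=0))
        def table_logp(tab):
            from math import lgamma
            n = tab.sum()
            const = (sum(lgamma(x + 1) for x in tab.sum(axis=1))
                     + sum(lgamma(x + 1) for x in tab.sum(axis=0))
                     - lgamma(n + 1))
            return const - sum(lgamma(x + 1) for x in tab.ravel())
        obs_logp = table_logp(t)
        n_mc = 20000
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(cols)
            tab = np.zeros((3, 2), dtype=int)
            np.add.at(tab, (rows, perm), 1)
            hits += table_logp(tab) <= obs_logp + 1e-9
        p_mc = hits / n_mc
        se = math.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(res["p"] - p_mc) < 3 * se

    def test_transpose_and_permutation_invariance(self, rng):
        t = rng.integers(1, 12, size=(3, 3))
        p0 = fisher_exact_rxc(t)["p"]
        assert fisher_exact_rxc(t.T)["p"] == pytest.approx(p0, rel=1e-9)
        perm = t[[2, 0, 1]][:, [1, 0, 2]]
        assert fisher_exact_rxc(perm)["p"] == pytest.approx(p0, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_rxc(np.array([[0, 0], [3, 4]]))

    def test_monte_carlo_fallback_close_to_exact(self):
        t = np.array([[20, 15, 12], [8, 22, 18]])
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, max_tables=1, n_mc=200_000, seed=1)
        assert mc["method"] == "monte-carlo"
        assert abs(mc["p"] - exact["p"]) < 4 * mc["se"] + 1e-3


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = np.arange(30.0)
        p, _ = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_small_disjoint_exact_enumeration(self):
        p, _ = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_p_decreases_with_shift(self, rng):
        x = rng.normal(size=100)
        ps = [wilcoxon_rank_sum(x, x + shift)[0] for shift in (0.2, 0.6, 1.2)]
        assert ps[0] > ps[1] > ps[2]


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3])[0] == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 4.0, 6.0])
        rho, _ = spearman(x, y)
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
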