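"""Coupling fits and group-statistics tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nvcouple import couplingstats as cs


class TestFitCoupling:
    def test_exact_line(self):
        g = np.linspace(5, 50, 10)
        fit = cs.fit_coupling(g, 0.03 * g + 0.31, measure="bold_pct")
        assert fit.gradient == pytest.approx(0.03)
        assert fit.intercept == pytest.approx(0.31)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_zero_gradient(self):
        fit = cs.fit_coupling(np.arange(10.0), np.full(10, 2.5))
        assert fit.gradient == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(20, 8, 10)
        y = rng.normal(1, 0.5, 10)
        fit = cs.fit_coupling(x, y)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.gradient == pytest.approx(beta[1])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cs.fit_coupling(np.full(10, 3.0), np.arange(10.0))

    def test_partial_eye_warns(self):
        with pytest.warns(UserWarning, match="5 points"):
            cs.fit_coupling(np.arange(5.0), np.arange(5.0), subject="p01")


def brute_force_mwu_p(x, y):
    """Exact two-tailed p by enumerating every group-1 label assignment."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    sums = np.array([sum(ranks[list(idx)]) for idx in
                     itertools.combinations(range(len(pooled)), n1)])
    lo = np.mean(sums <= r1 + 1e-9)
    hi = np.mean(sums >= r1 - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitneyExact:
    def test_separated_samples(self):
        res = cs.mannwhitney_exact([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2 / 20)  # 2 x 1/C(6,3)

    def test_identical_singletons(self):
        assert cs.mannwhitney_exact([1.0], [1.0]).p == 1.0

    def test_u_plus_uprime(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=12)
        u1 = cs.mannwhitney_exact(x, y).statistic
        u2 = cs.mannwhitney_exact(y, x).statistic
        assert u1 + u2 == pytest.approx(120.0)  # n1 * n2

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 8)
                                       for n2 in range(n1, 8)])
    def test_matches_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 31 + n2)
        # integers force ties with high probability
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        res = cs.mannwhitney_exact(x, y)
        assert res.p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=9)
        res = cs.mannwhitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.mannwhitney_exact([], [1.0])

    def test_normal_approximation_beyond_exact_limit(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = cs.mannwhitney_exact(x, y)
        assert res.method == "mann-whitney-normal"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_controlled(self):
        """Exact test at alpha=0.05 rejects at most ~5-7% of null samples."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x, y = rng.normal(size=10), rng.normal(size=14)
            rejections += cs.mannwhitney_exact(x, y).p < 0.05
        assert rejections / n_sim <= 0.07


class TestHolmBonferroni:
    def test_single_comparison(self):
        out = cs.holm_bonferroni([0.03])
        assert out["threshold"][0] == pytest.approx(0.05)
        assert out["reject"][0]

    def test_fourteen_comparison_thresholds(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 14)
        out = cs.holm_bonferroni(p)
        order = np.argsort(p)
        assert out["threshold"][order[0]] == pytest.approx(0.05 / 14)
        assert out["threshold"][order[12]] == pytest.approx(0.05 / 2)
        assert out["threshold"][order[13]] == pytest.approx(0.05)

    def test_step_down_stops_at_first_failure(self):
        out = cs.holm_bonferroni([0.001, 0.04, 0.011], alpha=0.05)
        # sorted: 0.001 < 0.05/3 (reject), 0.011 < 0.05/2 (reject),
        # 0.04 < 0.05 (reject)
        assert list(out["reject"]) == [True, True, True]
        out2 = cs.holm_bonferroni([0.001, 0.04, 0.03], alpha=0.05)
        # sorted: 0.001 rejects, 0.03 >= 0.025 stops the chain
        assert list(out2["reject"]) == [True, False, False]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_between_bonferroni_and_unadjusted(self, pvals):
        """Holm rejections contain Bonferroni's and are contained in the
        unadjusted-alpha rejections."""
        alpha = 0.05
        out = cs.holm_bonferroni(pvals, alpha)
        m = len(pvals)
        for p, rej in zip(pvals, out["reject"]):
            if p < alpha / m:       # Bonferroni rejects
                assert rej
            if rej:
                assert p < alpha

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cs.holm_bonferroni([1.2])
        with pytest.raises(ValueError):
            cs.holm_bonferroni([0.5], alpha=1.5)


def anova_oracle(data, groups):
    """Mixed-ANOVA F statistics via pingouin (independent implementation)."""
    import pandas as pd
    import pingouin as pg
    n, k = data.shape
    df = pd.DataFrame({
        "y": data.ravel(),
        "subject": np.repeat(np.arange(n), k),
        "within": np.tile(np.arange(k), n),
        "group": np.repeat(groups, k),
    })
    return pg.mixed_anova(df, dv="y", within="within", subject="subject",
                          between="group", correction=True)


class TestMixedAnova:
    def _data(self, seed=0, n1=6, n2=6, k=5, rho=0.0, scale=None):
        rng = np.random.default_rng(seed)
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        if scale is not None:
            s = np.sqrt(scale)
            cov = cov * np.outer(s, s)
        data = rng.multivariate_normal(np.zeros(k), cov, n1 + n2)
        data[n1:] += 1.0
        groups = np.array(["a"] * n1 + ["b"] * n2)
        return data, groups

    def test_epsilon_one_for_two_levels(self):
        data, groups = self._data(k=2)
        assert cs.gg_epsilon(data, groups) == 1.0

    def test_epsilon_near_one_under_compound_symmetry(self):
        data, groups = self._data(seed=1, n1=60, n2=60, rho=0.4)
        assert cs.gg_epsilon(data, groups) == pytest.approx(1.0, abs=0.08)

    def test_epsilon_bounds(self):
        for seed in range(5):
            data, groups = self._data(seed=seed,
                                      scale=[0.2, 1.0, 3.0, 9.0, 20.0])
            eps = cs.gg_epsilon(data, groups)
            assert 1.0 / 4 <= eps <= 1.0

    def test_matches_pingouin_oracle(self):
        data, groups = self._data(seed=3, scale=[0.5, 1.0, 2.0, 4.0, 8.0])
        res = cs.mixed_anova_gg(data, groups)
        ref = anova_oracle(data, groups).set_index("Source")
        assert res["group"].statistic == pytest.approx(ref.loc["group", "F"])
        assert res["within"].statistic == pytest.approx(
            ref.loc["within", "F"])
        assert res["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"])
        # epsilon pools the within-group (error) covariance; compare with
        # pingouin's estimator on group-centered data
        import pandas as pd
        import pingouin as pg
        centered = data.copy()
        for g in np.unique(groups):
            centered[groups == g] -= data[groups == g].mean(axis=0)
        assert res["within"].epsilon == pytest.approx(
            float(pg.epsilon(pd.DataFrame(centered), correction="gg")),
            abs=1e-6)

    def test_gg_correction_deflates_df(self):
        data, groups = self._data(seed=4, n1=10, n2=10,
                                  scale=[0.2, 1.0, 3.0, 9.0, 27.0])
        res = cs.mixed_anova_gg(data, groups)
        eps = res["within"].epsilon
        assert eps < 1.0
        if res["within"].method == "mixed-anova-gg":
            f = res["within"].statistic
            assert res["within"].df == pytest.approx((eps * 4, eps * 4 * 18))
            assert res["within"].p == pytest.approx(
                stats.f.sf(f, eps * 4, eps * 4 * 18))

    def test_simple_main_effects_match_scipy(self):
        data, groups = self._data(seed=5)
        out = cs.simple_main_effects(data, groups)
        for j, res in enumerate(out):
            f, p = stats.f_oneway(data[groups == "a", j],
                                  data[groups == "b", j])
            assert res.statistic == pytest.approx(f)
            assert res.p == pytest.approx(p)

    def test_unbalanced_groups_rejected(self):
        data = np.zeros((3, 5))
        with pytest.raises(ValueError):
            cs.mixed_anova_gg(data, np.array(["a", "a", "b"]))


class TestLogmar:
    def test_reference_standard_is_zero(self):
        assert cs.logmar(1.0) == 0.0

    def test_half_acuity(self):
        assert cs.logmar(0.5) == pytest.approx(math.log10(2), abs=1e-4)

    def test_one_line_increment(self):
        """One chart line changes acuity by 10^0.1, i.e. +0.1 log(MAR)."""
        a = 0.8
        assert cs.logmar(a / 10 ** 0.1) - cs.logmar(a) == pytest.approx(0.1)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cs.logmar(0.0)
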