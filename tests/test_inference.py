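"""Unit and property tests for the statistical core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

from redoxmr import (
    bh_fdr,
    correlate,
    linear_model,
    moderation,
    power_two_sample,
    two_group_test,
    wald_complete,
)
from redoxmr._errors import DataError, FitError
from redoxmr.inference import Z975, coef_from_ci

# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_separated_groups_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: U=0 and the exact two-sided p counts the two
        extreme arrangements among C(6,3)=20."""
        res = two_group_test([1, 2, 3], [4, 5, 6], method="mannwhitney")
        assert res.method == "mann_whitney_exact"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2 / 20)

    def test_identical_samples_symmetry(self):
        res = two_group_test([1, 2, 3], [1, 2, 3], method="mannwhitney")
        assert res.statistic == pytest.approx(3 * 3 / 2)
        assert res.p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration(self, seed):
        """Independent oracle: brute-force enumeration over label assignments,
        including tied data."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pooled = rng.integers(0, 4, n1 + n2).astype(float)  # heavy ties
        x, y = pooled[:n1], pooled[n1:]
        res = two_group_test(x, y, method="mannwhitney")

        ranks = sps.rankdata(pooled)
        mu = n1 * n2 / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        total = extreme = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            total += 1
            extreme += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        assert res.p == pytest.approx(extreme / total)

    def test_large_sample_against_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        res = two_group_test(x, y, method="mannwhitney")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestStudentT:
    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 25)
        res = two_group_test(x, y, method="t")
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_zero_variance_both_groups_errors(self):
        with pytest.raises(DataError, match="zero variance"):
            two_group_test([1, 1, 1], [2, 2, 2], method="t")

    def test_auto_select_picks_rank_test_for_skewed_data(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1.5, 200))
        y = np.exp(rng.normal(0.2, 1.5, 200))
        assert two_group_test(x, y).method.startswith("mann_whitney")
        a, b = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        assert two_group_test(a, b).method == "student_t"


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


class TestCorrelate:
    def test_linear_relation_gives_pearson_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_monotone_invariance_of_spearman(self):
        x = np.linspace(0, 3, 25)
        res_s = correlate(x, np.exp(x), method="spearman")
        res_p = correlate(x, np.exp(x), method="pearson")
        assert res_s.statistic == pytest.approx(1.0)
        assert res_p.statistic < 1.0

    def test_tied_data_matches_hand_midranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 5.0, 5.0])
        # midranks by hand: x -> 1.5 1.5 3 4.5 4.5 6 ; y -> 3 1.5 1.5 4 5.5 5.5
        rx_ = np.array([1.5, 1.5, 3, 4.5, 4.5, 6])
        ry = np.array([3, 1.5, 1.5, 4, 5.5, 5.5])
        expected = np.corrcoef(rx_, ry)[0, 1]
        assert correlate(x, y, method="spearman").statistic == pytest.approx(expected)

    def test_pvalue_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = correlate(x, y)
        ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(DataError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


class TestBhFdr:
    def test_hand_step_up(self):
        # q_(i) = min over j>=i of p_(j)*m/j: all become 0.04
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_empty_errors(self):
        with pytest.raises(DataError):
            bh_fdr([])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=40))
    def test_qvalues_dominate_p_and_are_monotone(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_hand_step_up_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 15))
            m = len(p)
            # independent oracle: literal min_{j>=i} p_(j) m / j
            order = np.argsort(p)
            ps = p[order]
            expected_sorted = [
                min(ps[j] * m / (j + 1) for j in range(i, m)) for i in range(m)
            ]
            expected = np.empty(m)
            expected[order] = np.minimum(expected_sorted, 1.0)
            assert bh_fdr(p) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# linear model & moderation
# ---------------------------------------------------------------------------


class TestLinearModel:
    def test_univariate_standardized_beta_is_pearson_r(self, rng):
        x = rng.normal(size=60)
        y = 1.5 * x + rng.normal(size=60)
        fit = linear_model(y, x)
        r = correlate(x, y).statistic
        assert fit.standardized_betas[1] == pytest.approx(r, abs=1e-10)

    def test_three_point_closed_form(self):
        # x=(0,1,2), y=(1,2,4): Sxy/Sxx = 3/2, intercept = 7/3 - 3/2 = 5/6
        fit = linear_model([1.0, 2.0, 4.0], [0.0, 1.0, 2.0], bootstrap_policy="never")
        assert fit.coefficients == pytest.approx([5 / 6, 1.5])

    def test_zero_residuals_flagged(self):
        x = np.arange(8.0)
        fit = linear_model(2 * x + 3, x, bootstrap_policy="never")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.zero_residual

    def test_rank_deficiency_names_aliased_column(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(FitError, match="b_dup"):
            linear_model(rng.normal(size=30), X, names=["a", "b_dup"])

    def test_levene_trigger_flags_heteroscedasticity(self, rng):
        x = np.linspace(0, 1, 400)
        y = x + rng.normal(size=400) * (0.1 + 2 * x)
        fit = linear_model(y, x, n_boot=200, seed=5)
        assert fit.heteroscedastic and fit.bootstrap_used
        assert fit.bootstrap_cis is not None

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=50)
        fit = linear_model(y, X, bootstrap_policy="never")
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.coefficients == pytest.approx(ref.params, rel=1e-8)
        assert fit.ses == pytest.approx(ref.bse, rel=1e-8)
        assert fit.ps == pytest.approx(ref.pvalues, rel=1e-6)


class TestModeration:
    def test_interaction_matches_normal_equations_oracle(self, rng):
        """The fitted interaction equals the hand-solved normal equations of
        the y ~ x + m + x·m design (checked on a tiny replicated dataset that
        satisfies the per-stratum size guard)."""
        y6 = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 7.0])
        x6 = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        m6 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        # replicate the 6-row table 4x: same normal-equations solution
        y, x, m = np.tile(y6, 4), np.tile(x6, 4), np.tile(m6, 4)
        M = np.column_stack([np.ones(len(y)), x, m, x * m])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        res = moderation(y, x, m, n_boot=0)
        assert res.interaction_b == pytest.approx(beta[3], abs=1e-10)

    def test_stratum_size_guard(self):
        y = np.arange(12.0)
        x = np.arange(12.0)
        m = np.array([0] * 2 + [1] * 10)
        with pytest.raises(DataError, match="stratum"):
            moderation(y, x, m, n_boot=0)

    def test_interaction_recovered_with_ci(self, rng):
        n = 400
        x = rng.normal(size=n)
        m = (rng.random(n) < 0.5).astype(float)
        y = 1.0 + 0.5 * x + 0.2 * m - 0.8 * x * m + rng.normal(0, 0.5, n)
        res = moderation(y, x, m, n_boot=400, seed=9)
        assert res.ci[0] <= res.interaction_b <= res.ci[1]
        assert res.interaction_b == pytest.approx(-0.8, abs=0.15)
        assert res.ci[1] < 0  # negative interaction detected


# ---------------------------------------------------------------------------
# Wald utilities & power
# ---------------------------------------------------------------------------


class TestWald:
    def test_degenerate_ci_errors(self):
        with pytest.raises(DataError):
            wald_complete(ci=(1.0, 1.0))
        with pytest.raises(DataError):
            wald_complete(ci=(-1.0, 2.0))

    def test_roundtrip_identity(self, rng):
        for _ in range(50):
            log_hr = rng.normal(0, 1)
            se = rng.uniform(0.05, 1.0)
            t1 = wald_complete(log_hr=log_hr, se=se)
            t2 = wald_complete(ci=t1.ci)
            assert t2.hr == pytest.approx(math.exp(log_hr), abs=1e-12, rel=1e-12)
            assert t2.se == pytest.approx(se, abs=1e-12, rel=1e-12)

    def test_linear_scale_ci_inversion(self):
        b, se, p = coef_from_ci(-3.15, -0.01)
        assert b == pytest.approx(-1.58)
        assert b - Z975 * se == pytest.approx(-3.15)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = power_two_sample(0.0, 1.0, 50, 50, alpha=0.05)
        assert spec.power == pytest.approx(0.05)

    def test_matches_numerical_integration(self):
        """Quadrature oracle: P(|Z + ncp| > z_a) with Z standard normal."""
        delta, sd, n1, n2, alpha = 0.1, 0.28, 50, 50, 0.05
        se = sd * math.sqrt(1 / n1 + 1 / n2)
        za = sps.norm.ppf(1 - alpha / 2)

        def integrand(z):
            return sps.norm.pdf(z) * ((z + delta / se > za) or (z + delta / se < -za))

        oracle, _ = integrate.quad(integrand, -12, 12, limit=400)
        spec = power_two_sample(delta, sd, n1, n2, alpha)
        assert spec.power == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_effect_and_sample_size(self):
        base = power_two_sample(0.3, 1.0, 30, 30).power
        assert power_two_sample(0.6, 1.0, 30, 30).power >= base
        assert power_two_sample(0.3, 1.0, 90, 30).power >= base
        assert power_two_sample(0.3, 1.0, 30, 90).power >= base
        assert power_two_sample(50.0, 1.0, 30, 30).power == pytest.approx(1.0)
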