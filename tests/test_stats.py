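"""Statistics battery: SNR, CV, Friedman/Kendall-w, Wilcoxon, Holm,
Lilliefors, ICC(2,1) — each against an independent oracle where one exists."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import stats as spstats

from septrial.stats import (coefficient_of_variation, friedman, holm_adjust,
                            icc_21, icc_interpretation, kendalls_w, lilliefors,
                            snr_mean_std, wilcoxon_signed_rank)

# ---------------------------------------------------------------------------
# Independent oracles (coded from the definitions, not the implementation)


def oracle_friedman_chi2(matrix):
    """Friedman statistic straight from column rank sums (no tie correction)."""
    n, k = matrix.shape
    ranks = np.array([spstats.rankdata(row) for row in matrix])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float((rj ** 2).sum()) - 3.0 * n * (k + 1)


def oracle_friedman_exact_p(matrix):
    """Exact p by enumerating every within-row ordering of the observed values."""
    n, k = matrix.shape
    obs = oracle_friedman_chi2(matrix)
    count = total = 0
    for perms in itertools.product(itertools.permutations(range(k)), repeat=n):
        perm_matrix = np.array([matrix[i, list(p)] for i, p in enumerate(perms)])
        count += oracle_friedman_chi2(perm_matrix) >= obs - 1e-12
        total += 1
    return count / total


def oracle_wilcoxon_exact_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = spstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    p_ge = (ws >= w_obs - 1e-12).mean()
    p_le = (ws <= w_obs + 1e-12).mean()
    return min(1.0, 2.0 * min(p_ge, p_le))


# ---------------------------------------------------------------------------


class TestSnrAndCv:
    def test_snr_worked_example(self):
        assert snr_mean_std([2.0, 4.0, 6.0]) == pytest.approx(2.0)

    @given(hst.floats(0.1, 100))
    def test_snr_scale_invariant(self, c):
        base = snr_mean_std([2.0, 4.0, 6.0])
        assert snr_mean_std([2 * c, 4 * c, 6 * c]) == pytest.approx(base)

    def test_snr_constant_rejected(self):
        with pytest.raises(ValueError):
            snr_mean_std([3.0, 3.0, 3.0])

    def test_cv_examples(self):
        assert coefficient_of_variation([10.0, 10.0, 10.0]) == 0.0
        assert coefficient_of_variation([5.0, 15.0]) == pytest.approx(0.7071, abs=1e-4)

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_cohort_target_intensity_cv_matches_population(self):
        from septrial import synth
        cohort = synth.sample_cohort(200, seed=3)
        for pw in (0.1, 0.5, 1.0):
            cv = coefficient_of_variation([s.snap_thresholds[pw] for s in cohort])
            assert cv == pytest.approx(0.10, abs=0.03)


class TestFriedman:
    def test_fully_concordant_exact(self):
        res = friedman(np.array([[1, 2, 3]] * 3, dtype=float))
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(6 / 216)
        assert res.method == "friedman-exact"

    def test_balanced_columns_give_zero(self):
        mat = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2]], dtype=float)
        assert friedman(mat).statistic == pytest.approx(0.0)

    def test_row_shift_invariance(self, rng):
        mat = rng.standard_normal((6, 3))
        shifted = mat.copy()
        shifted[2] += 100.0
        assert friedman(mat).statistic == pytest.approx(friedman(shifted).statistic)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        mat = r.standard_normal((4, 3))
        res = friedman(mat)
        assert res.statistic == pytest.approx(oracle_friedman_chi2(mat))
        assert res.p_value == pytest.approx(oracle_friedman_exact_p(mat))

    def test_matches_scipy_on_tie_free_data(self, rng):
        mat = rng.standard_normal((20, 3))
        res = friedman(mat)
        chi2, p = spstats.friedmanchisquare(*mat.T)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_missing_rows_dropped_and_counted(self):
        mat = np.array([[1, 2, 3], [2, 3, 4], [np.nan, 1, 2],
                        [3, 4, 5], [4, 5, 6], [5, 6, 7], [6, 7, 8]])
        res = friedman(mat)
        assert res.extras["n_dropped"] == 1
        assert res.n == 6

    def test_kendalls_w_attached_matches_direct_concordance(self, rng):
        # On tie-free data w equals the normalized variance of rank sums.
        mat = rng.standard_normal((8, 4))
        res = friedman(mat)
        n, k = mat.shape
        ranks = np.array([spstats.rankdata(row) for row in mat])
        rj = ranks.sum(axis=0)
        s = ((rj - n * (k + 1) / 2) ** 2).sum()
        w_direct = 12.0 * s / (n ** 2 * (k ** 3 - k))
        assert res.effect_size == pytest.approx(w_direct, rel=1e-9)


class TestKendallsW:
    def test_reported_values(self):
        assert round(kendalls_w(8.17, 12, 3), 2) == 0.34
        assert round(kendalls_w(17.64, 11, 3), 2) == 0.80

    def test_zero_statistic(self):
        assert kendalls_w(0.0, 12, 3) == 0.0

    def test_maximum_concordance(self):
        assert kendalls_w(24.0, 12, 3) == 1.0

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(1.0, 0, 3)
        with pytest.raises(ValueError):
            kendalls_w(-1.0, 5, 3)


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_signed_rank(y, x).p_value)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_p_matches_sign_pattern_enumeration(self, n):
        r = np.random.default_rng(n)
        d = np.round(r.normal(0.4, 1.0, n), 1)   # rounding forces rank ties
        d = d[d != 0]
        if d.size < 3:
            pytest.skip("degenerate draw")
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(oracle_wilcoxon_exact_p(d))

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.standard_normal(15)
        res = wilcoxon_signed_rank(d)
        ref = spstats.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self, rng):
        d = rng.standard_normal(60) + 0.3
        res = wilcoxon_signed_rank(d)
        ref = spstats.wilcoxon(d, method="approx", correction=False)
        assert res.method == "wilcoxon-normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestHolm:
    def test_worked_example(self):
        out = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=8))
    def test_adjusted_never_below_raw(self, ps):
        out = holm_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        assert np.all(out <= 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=7)
        assert np.allclose(holm_adjust(p), multipletests(p, method="holm")[1])


class TestLilliefors:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(500)
            hits += lilliefors(x).p_value > 0.05
        assert hits >= 90

    def test_uniform_samples_usually_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).uniform(size=500)
            hits += lilliefors(x).p_value < 0.05
        assert hits >= 90

    def test_statistic_affine_invariant(self, rng):
        x = rng.standard_normal(100)
        d1 = lilliefors(x).statistic
        d2 = lilliefors(5.0 * x - 3.0).statistic
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_statistic_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        x = rng.standard_normal(200)
        d_sm, _ = sm_lilliefors(x, dist="norm")
        assert lilliefors(x).statistic == pytest.approx(d_sm, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors([1.0, 2.0, 3.0])


class TestIcc:
    def test_hand_computed_anova_example(self):
        res = icc_21(np.array([[1, 2], [3, 4], [5, 6]], dtype=float))
        assert res.extras["msr"] == pytest.approx(8.0)
        assert res.extras["msc"] == pytest.approx(1.5)
        assert res.extras["mse"] == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(8.0 / 9.0)

    def test_identical_sessions_give_unity(self):
        x = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0], [2.0, 2.0]])
        assert icc_21(x).effect_size == pytest.approx(1.0)

    def test_shuffled_sessions_destroy_agreement(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 300)
        x = np.column_stack([vals, rng.permutation(vals)])
        assert abs(icc_21(x).effect_size) < 0.2

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        x = rng.normal(0, 1, (15, 3)) + rng.normal(0, 1, (15, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "session": np.tile(np.arange(3), 15),
            "value": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="session",
                                 ratings="value").set_index("Type").loc["ICC(A,1)"]
        res = icc_21(x)
        assert res.effect_size == pytest.approx(ref["ICC"], abs=1e-6)
        assert res.p_value == pytest.approx(ref["pval"], rel=1e-3)
        ci = list(ref["CI95"])
        assert res.ci[0] == pytest.approx(ci[0], abs=0.01)
        assert res.ci[1] == pytest.approx(ci[1], abs=0.01)

    def test_no_between_subject_variance_reported_not_clamped(self, rng):
        x = np.tile([[0.0, 1.0]], (6, 1)) + rng.normal(0, 0.01, (6, 2))
        assert icc_21(x).effect_size <= 0.2

    def test_interpretation_bands(self):
        assert icc_interpretation(0.3) == "poor"
        assert icc_interpretation(0.6) == "moderate"
        assert icc_interpretation(0.8) == "good"
        assert icc_interpretation(0.95) == "excellent"

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_21(np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]]))
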