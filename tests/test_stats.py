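"""Mann-Whitney tests, BH-FDR, boxplot summaries, region comparison."""

import numpy as np
import pytest
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from ceplane import (
    QuantifierPoint,
    bh_fdr,
    boxplot_summary,
    compare_region,
    h_index,
    mann_whitney_u,
)


def as_points(values, D=6):
    return [
        QuantifierPoint(H=v, C=v / 2, D=D, N=720, window_index=i, channel_id="x")
        for i, v in enumerate(values)
    ]


class TestMannWhitney:
    def test_exact_p_for_fully_separated_triples(self):
        # all 3 ranks of `a` below `b`: U_min = 0, exact two-sided p = 2/20
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15) + 0.5
        _, p_raw = mann_whitney_u(a, b)
        _, p_exp = mann_whitney_u(np.exp(a), np.exp(b))
        assert p_raw == pytest.approx(p_exp, abs=1e-14)

    def test_exact_and_corrected_normal_agree_at_n8(self, rng):
        # tie-free samples with nA = nB = 8: the corrected normal
        # approximation stays within 0.011 of the exact p (the worst case
        # over all 33 possible U values is 0.0109)
        for _ in range(25):
            a = rng.normal(size=8)
            b = rng.normal(size=8) + rng.normal() * 0.5
            _, p_exact = mann_whitney_u(a, b)  # exact branch
            p_approx = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="asymptotic").pvalue
            assert p_exact == pytest.approx(p_approx, abs=0.011)

    def test_large_or_tied_samples_use_corrected_approximation(self, rng):
        a = np.round(rng.normal(size=30), 1)  # rounding induces ties
        b = np.round(rng.normal(size=30) + 0.3, 1)
        _, p = mann_whitney_u(a, b)
        p_ref = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, abs=1e-14)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHIndex:
    @pytest.mark.parametrize("p, expected", [(0.01, 1), (0.05, 0), (0.81, 0)])
    def test_strict_threshold(self, p, expected):
        assert h_index(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h_index(1.5)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        adjusted, decisions = bh_fdr([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.05, 0.05])
        np.testing.assert_array_equal(decisions, [True, True, False, False])

    def test_single_p_unchanged(self):
        adjusted, _ = bh_fdr([0.037])
        assert adjusted[0] == pytest.approx(0.037)

    def test_all_equal_p_unchanged(self):
        adjusted, _ = bh_fdr([0.03] * 6)
        np.testing.assert_allclose(adjusted, 0.03)

    def test_matches_independent_implementation(self, rng):
        # cross-check against statsmodels on 100 random p-vectors
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            adjusted, _ = bh_fdr(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(adjusted, ref, atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=25)
        adjusted, _ = bh_fdr(p)
        assert np.all(adjusted >= p - 1e-15)


class TestBoxplotSummary:
    def test_hand_computed_quartiles_for_1_to_100(self):
        box = boxplot_summary(np.arange(1.0, 101.0))
        assert box.median == 50.5
        assert box.q1 == 25.75
        assert box.q3 == 75.25
        assert box.n == 100

    def test_constant_sample_degenerates(self):
        box = boxplot_summary(np.full(10, 3.3))
        assert box.q1 == box.q3 == box.median == 3.3
        assert box.notch_lo == box.notch_hi == 3.3
        assert len(box.outliers) == 0

    def test_notch_width_shrinks_as_inverse_sqrt_n(self):
        # linspace samples have exact 0.25/0.75 quartiles for any n, so the
        # IQR is fixed and only the 1/sqrt(n) factor changes
        small = boxplot_summary(np.linspace(0.0, 1.0, 50))
        big = boxplot_summary(np.linspace(0.0, 1.0, 200))
        assert big.q3 - big.q1 == pytest.approx(small.q3 - small.q1)
        assert big.notch_hi - big.notch_lo == pytest.approx(
            (small.notch_hi - small.notch_lo) / 2, rel=1e-12
        )

    def test_outliers_beyond_tukey_fences(self):
        sample = np.concatenate([np.arange(1.0, 21.0), [100.0]])
        box = boxplot_summary(sample)
        np.testing.assert_array_equal(box.outliers, [100.0])
        assert box.whisker_hi == 20.0


class TestCompareRegion:
    def test_same_points_not_significant(self, rng):
        pts = as_points(rng.normal(size=20))
        result = compare_region(pts, pts, "H")
        assert result.h == 0
        assert result.mean_f == result.mean_m

    def test_separated_cohorts_detected(self, rng):
        f = as_points(rng.normal(loc=0.7, scale=0.02, size=40))
        m = as_points(rng.normal(loc=0.6, scale=0.02, size=40))
        result = compare_region(f, m, "H", region="r", hemisphere="L")
        assert result.h == 1
        assert result.n_f == result.n_m == 40
        assert result.mean_f > result.mean_m

    def test_summary_statistics_match_numpy(self, rng):
        vals = rng.normal(size=15)
        result = compare_region(as_points(vals), as_points(rng.normal(size=9)), "C")
        assert result.mean_f == pytest.approx(np.mean(vals / 2))
        assert result.median_f == pytest.approx(np.median(vals / 2))
        assert result.sd_f == pytest.approx(np.std(vals / 2, ddof=1))

    def test_empty_side_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_region([], as_points(rng.normal(size=5)), "H")

    def test_unknown_quantifier_rejected(self, rng):
        pts = as_points(rng.normal(size=5))
        with pytest.raises(ValueError):
            compare_region(pts, pts, "Z")

    def test_disjoint_notches_cooccur_with_rejection(self, rng):
        # the two evidence styles (notches, U test) agree on clearly
        # separated cohorts in > 90% of runs
        agree = 0
        n_runs = 100
        for _ in range(n_runs):
            f_vals = rng.normal(loc=0.70, scale=0.03, size=40)
            m_vals = rng.normal(loc=0.66, scale=0.03, size=40)
            res = compare_region(as_points(f_vals), as_points(m_vals), "H")
            box_f = boxplot_summary(f_vals)
            box_m = boxplot_summary(m_vals)
            disjoint = box_f.notch_lo > box_m.notch_hi or box_m.notch_lo > box_f.notch_hi
            agree += (disjoint and res.h == 1) or (not disjoint and res.h == 0)
        assert agree > 0.9 * n_runs
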