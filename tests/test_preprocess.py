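"""Per-slide preprocessing: rLsBC, replicate averaging, outlier
exclusion, M-A normalization and the loop-design filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcmarray import preprocess as pp
from gcmarray.loess import loess_fit


def _slide(F_R, B_R, F_G, B_G, ids=None):
    n = len(F_R)
    return pp.TwoChannelSlide(
        feature_id=np.array(ids if ids is not None else [f"f{i}" for i in range(n)], dtype=object),
        F_R=np.asarray(F_R, float),
        B_R=np.asarray(B_R, float),
        F_G=np.asarray(F_G, float),
        B_G=np.asarray(B_G, float),
    )


class TestLoess:
    def test_constant_response_reproduced(self, rng):
        x = rng.uniform(0, 10, 100)
        fit = loess_fit(x, np.full(100, 3.5), span=0.3)
        assert np.allclose(fit, 3.5, atol=1e-12)

    @pytest.mark.parametrize("degree", [1, 2])
    def test_exact_line_reproduced(self, rng, degree):
        x = rng.uniform(0, 10, 200)
        y = 2.0 - 0.5 * x
        fit = loess_fit(x, y, span=0.3, degree=degree)
        assert np.abs(fit - y).max() < 1e-9

    def test_exact_quadratic_reproduced(self, rng):
        x = rng.uniform(6, 16, 300)
        y = 0.5 - 0.2 * x + 0.01 * x**2
        fit = loess_fit(x, y, span=0.10, degree=2)
        assert np.abs(fit - y).max() < 1e-9

    def test_window_too_small_raises(self, rng):
        x = rng.uniform(0, 1, 50)
        with pytest.raises(ValueError, match="span"):
            loess_fit(x, x, span=0.02, degree=2)

    def test_nan_pairs_propagate(self, rng):
        x = rng.uniform(0, 10, 60)
        y = x.copy()
        y[5] = np.nan
        fit = loess_fit(x, y, span=0.5)
        assert np.isnan(fit[5]) and np.isfinite(np.delete(fit, 5)).all()


class TestBackgroundCorrection:
    def test_constant_background_subtracted(self, rng):
        F = rng.uniform(8, 14, 80)
        slide = _slide(F, np.full(80, 4.0), F + 1, np.full(80, 4.0))
        corr = pp.background_correct_rlsbc(slide)
        assert np.allclose(corr.Bl_R, 4.0, atol=1e-10)
        assert np.allclose(corr.Fc_R, F - 4.0, atol=1e-10)

    def test_linear_background_removed_exactly(self, rng):
        F = rng.uniform(8, 14, 120)
        B = 1.5 + 0.3 * F
        slide = _slide(F, B, F, B)
        corr = pp.background_correct_rlsbc(slide)
        assert np.abs(corr.Fc_G - (F - B)).max() < 1e-9

    def test_fc_is_two_to_the_Fc(self, rng):
        F = rng.uniform(8, 14, 80)
        slide = _slide(F, np.full(80, 1.0), F, np.full(80, 1.0))
        corr = pp.background_correct_rlsbc(slide)
        assert np.allclose(corr.fc_R, np.exp2(corr.Fc_R))
        # Fc = 3 -> fc = 8 on the absolute scale
        assert np.exp2(3.0) == 8.0

    def test_too_few_features_names_channel(self):
        slide = _slide(np.arange(5.0), np.ones(5), np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="channel R"):
            pp.background_correct_rlsbc(slide)


class TestAverageReplicates:
    def _corrected(self, fc_values, ids=None):
        Fc = np.log2(np.asarray(fc_values, float))
        n = len(Fc)
        return pp.CorrectedSlide(
            feature_id=np.array(ids or [f"f{i}" for i in range(n)], dtype=object),
            Bl_R=np.zeros(n), Bl_G=np.zeros(n), Fc_R=Fc, Fc_G=Fc,
        )

    @pytest.mark.parametrize(
        "reps,expected",
        [((8.0, 1.0, 1.0), 2.0), ((5.0, 5.0, 5.0), 5.0), ((2.0, 8.0), 4.0)],
    )
    def test_geometric_mean_examples(self, reps, expected):
        slides = [self._corrected([v] * 4) for v in reps]
        avg = pp.average_replicates(slides)
        assert np.allclose(avg.fa_R, expected)
        assert np.allclose(avg.fa_G, expected)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        base = [np.array([2.0, 4.0, 9.0]), np.array([3.0, 5.0, 1.0])]
        plain = pp.average_replicates([self._corrected(v) for v in base])
        scaled = pp.average_replicates([self._corrected(v * c) for v in base])
        assert np.allclose(scaled.fa_R, plain.fa_R * c, rtol=1e-9)

    def test_missing_in_one_of_three_keeps_feature(self):
        s1 = self._corrected([2.0, 2.0, 2.0, 2.0])
        s2 = self._corrected([8.0, 8.0, 8.0, 8.0])
        s3 = self._corrected([2.0, 2.0, 2.0, 2.0])
        s3.Fc_R[0] = np.nan
        avg = pp.average_replicates([s1, s2, s3])
        assert avg.mask[0]  # two replicates remain
        assert np.isclose(avg.fa_R[0], 4.0)  # sqrt(2*8)

    def test_missing_in_two_of_three_masks_feature(self):
        slides = [self._corrected([2.0, 2.0, 2.0, 2.0]) for _ in range(3)]
        slides[0].Fc_G[1] = np.nan
        slides[1].Fc_G[1] = np.nan
        avg = pp.average_replicates(slides)
        assert not avg.mask[1]

    def test_mismatched_features_raise(self):
        s1 = self._corrected([1.0] * 4, ids=list("abcd"))
        s2 = self._corrected([1.0] * 4, ids=list("abce"))
        with pytest.raises(ValueError, match="feature space"):
            pp.average_replicates([s1, s2])


class TestOutlierIQR:
    def test_gaussian_exclusion_rate_tiny(self, rng):
        # at 3 IQR beyond the quartiles, N(0,1) mass outside is ~2e-6
        vals = rng.normal(0, 1, 100_000)
        keep = pp.remove_outliers_iqr(vals, k_iqr=3.0, iterative=True)
        assert (~keep).mean() < 0.001

    def test_single_extreme_value_removed(self, rng):
        vals = rng.uniform(6, 16, 99)
        vals = np.append(vals, np.log2(1e6) * 10)  # absurd intensity
        keep = pp.remove_outliers_iqr(vals, k_iqr=3.0)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_constant_vector_all_kept(self):
        keep = pp.remove_outliers_iqr(np.full(10, 7.0))
        assert keep.all()

    def test_iterative_reaches_fixed_point(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 50), [50.0, 55.0]])
        keep = pp.remove_outliers_iqr(vals, k_iqr=3.0, iterative=True)
        again = pp.remove_outliers_iqr(vals[keep], k_iqr=3.0, iterative=True)
        assert again.all()

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            pp.remove_outliers_iqr(np.array([1.0, 2.0, np.nan, np.nan]))


class TestComputeMA:
    def test_equal_channels_zero_M(self):
        prof = pp.compute_ma(np.array([4.0, 7.0]), np.array([4.0, 7.0]))
        assert np.allclose(prof.M, 0.0)

    def test_forced_example(self):
        prof = pp.compute_ma(np.array([4.0]), np.array([1.0]))
        assert prof.M[0] == 2.0 and prof.A[0] == 1.0

    def test_channel_swap_negates_M_keeps_A(self, rng):
        r, g = rng.uniform(1, 100, 30), rng.uniform(1, 100, 30)
        a = pp.compute_ma(r, g)
        b = pp.compute_ma(g, r)
        assert np.allclose(a.M, -b.M) and np.allclose(a.A, b.A)

    def test_nonpositive_masked(self):
        prof = pp.compute_ma(np.array([4.0, 0.0, -1.0]), np.array([1.0, 2.0, 2.0]))
        assert np.isnan(prof.M[1]) and np.isnan(prof.M[2])


class TestNormalizeLoessMA:
    def test_zero_M_stays_zero(self, rng):
        prof = pp.RatioProfile(
            feature_id=np.arange(100).astype(object),
            M=np.zeros(100),
            A=rng.uniform(6, 16, 100),
        )
        out = pp.normalize_loess_ma(prof)
        assert np.abs(out.M).max() < 1e-12
        assert np.array_equal(out.A, prof.A)

    def test_exact_quadratic_bias_removed(self, rng):
        A = rng.uniform(6, 16, 400)
        M = 1.0 - 0.3 * A + 0.02 * A**2
        prof = pp.RatioProfile(
            feature_id=np.arange(400).astype(object), M=M, A=A
        )
        out = pp.normalize_loess_ma(prof, span=0.10, degree=2)
        assert np.abs(out.M).max() < 1e-6

    def test_noisy_bias_shrinks_and_residual_trend_flat(self, rng):
        A = rng.uniform(6, 16, 500)
        M = 0.8 - 0.25 * A + 0.015 * A**2 + rng.normal(0, 0.1, 500)
        prof = pp.RatioProfile(feature_id=np.arange(500).astype(object), M=M, A=A)
        out = pp.normalize_loess_ma(prof)
        assert abs(np.median(out.M)) < abs(np.median(M))
        refit = loess_fit(A, out.M, span=0.10, degree=2)
        assert np.abs(refit).max() < 0.05

    def test_idempotent_on_pure_trend(self, rng):
        # when the first pass removes the whole trend, a second pass
        # is a no-op
        A = rng.uniform(6, 16, 300)
        M = 1.2 - 0.4 * A + 0.02 * A**2
        prof = pp.RatioProfile(feature_id=np.arange(300).astype(object), M=M, A=A)
        once = pp.normalize_loess_ma(prof)
        twice = pp.normalize_loess_ma(once)
        assert np.abs(twice.M - once.M).max() < 1e-9

    def test_second_pass_is_contraction_on_noisy_data(self, rng):
        A = rng.uniform(6, 16, 300)
        M = 0.5 * np.sin(A) + rng.normal(0, 0.2, 300)
        prof = pp.RatioProfile(feature_id=np.arange(300).astype(object), M=M, A=A)
        once = pp.normalize_loess_ma(prof)
        twice = pp.normalize_loess_ma(once)
        first_change = np.abs(once.M - prof.M).max()
        second_change = np.abs(twice.M - once.M).max()
        assert second_change < 0.5 * first_change


class TestLoopFilter:
    def _profiles(self, M1, M2, M3):
        n = len(M1)
        ids = np.array([f"f{i}" for i in range(n)], dtype=object)
        A = np.linspace(6, 16, n)
        return tuple(
            pp.RatioProfile(feature_id=ids, M=np.asarray(m, float), A=A)
            for m in (M1, M2, M3)
        )

    def test_consistent_triple_all_kept(self, rng):
        M1, M2 = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        p1, p2, p3 = self._profiles(M1, M2, M1 + M2)
        res = pp.loop_design_filter(p1, p2, p3)
        assert np.abs(res.ldf).max() == 0.0
        assert res.keep.all()

    def test_gaussian_ldf_retained_fraction(self, rng):
        # keep within mean +/- 2 SD of a normal: ~95.45%
        n = 40_000
        M1, M2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        M3 = M1 + M2 - rng.normal(0, 0.5, n)
        p1, p2, p3 = self._profiles(M1, M2, M3)
        res = pp.loop_design_filter(p1, p2, p3, n_sd=2.0)
        assert res.keep.mean() == pytest.approx(0.9545, abs=0.005)

    def test_single_perturbed_feature_removed(self, rng):
        n = 200
        M1, M2 = rng.normal(0, 0.1, n), rng.normal(0, 0.1, n)
        M3 = M1 + M2 + rng.normal(0, 0.05, n)
        M3[17] += 10 * 0.05 * 10  # gross loop violation
        p1, p2, p3 = self._profiles(M1, M2, M3)
        res = pp.loop_design_filter(p1, p2, p3)
        assert not res.keep[17]
        assert res.keep.sum() >= n - 5

    def test_keep_rule_matches_invariant(self, rng):
        n = 500
        M1, M2, M3 = (rng.normal(0, 1, n) for _ in range(3))
        p1, p2, p3 = self._profiles(M1, M2, M3)
        res = pp.loop_design_filter(p1, p2, p3, n_sd=2.0)
        expected = np.abs(res.ldf - res.mean_ldf) <= 2.0 * res.sd_ldf
        assert np.array_equal(res.keep, expected)

    def test_consistent_shift_invariance(self, rng):
        n = 300
        M1, M2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        M3 = M1 + M2 + rng.normal(0, 0.3, n)
        base = pp.loop_design_filter(*self._profiles(M1, M2, M3))
        shifted = pp.loop_design_filter(*self._profiles(M1 + 5, M2 - 2, M3 + 3))
        assert np.array_equal(base.keep, shifted.keep)

    def test_mismatched_features_error(self, rng):
        p1, p2, p3 = self._profiles(*(rng.normal(0, 1, 50) for _ in range(3)))
        p3.feature_id = np.array([f"g{i}" for i in range(50)], dtype=object)
        with pytest.raises(ValueError, match="asymmetric difference"):
            pp.loop_design_filter(p1, p2, p3)
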