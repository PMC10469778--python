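"""Correlation grids, extrema, wavelet maps, LME/LRT, and Tukey contrasts."""

import numpy as np
import pytest

from speechbeta.epochs import BandPowerTimecourse, canonical_grid
from speechbeta.inference import (
    bonferroni_threshold,
    cv_centered_correlations,
    gaussian_wavelet_map,
    interval_correlations,
    interval_lme_lrt,
    last_pre_onset_change_point,
    local_extrema,
    tukey_pairwise,
)

FS = 1000.0


def make_tc(values, band="beta_l"):
    _, boundaries = canonical_grid(FS)
    return BandPowerTimecourse(
        band=band, values=np.asarray(values, float), boundaries=boundaries,
        sample_rate_hz=FS,
    )


def canonical_series(rng=None):
    n = sum(canonical_grid(FS)[0])
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * 1.3 * t)
    if rng is not None:
        x = x + 0.05 * rng.standard_normal(n)
    return x


class TestBonferroni:
    def test_study_constants(self):
        # alpha = 0.05 over the 15 unique sub-band pairs
        assert bonferroni_threshold(0.05, 15) == pytest.approx(1 / 300)
        assert round(bonferroni_threshold(0.05, 15), 3) == 0.003

    def test_single_comparison_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)

    @pytest.mark.parametrize("alpha,m", [(0.0, 5), (1.2, 5), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, m):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, m)


class TestIntervalCorrelations:
    def test_self_and_anti_correlation(self, rng):
        x = canonical_series(rng)
        tcs = {
            "a": make_tc(x),
            "b": make_tc(x.copy()),
            "c": make_tc(-x),
        }
        grid = interval_correlations(tcs, "vowel")
        assert grid.pair("a", "b")[0] == pytest.approx(1.0)
        assert grid.pair("a", "c")[0] == pytest.approx(-1.0)

    def test_fifteen_unique_pairs_for_six_bands(self, rng):
        tcs = {
            f"band{i}": make_tc(canonical_series(rng) + 0.1 * i) for i in range(6)
        }
        grid = interval_correlations(tcs, "ISP1")
        assert grid.m == 15
        assert grid.alpha_critical == pytest.approx(0.05 / 15)
        assert grid.to_frame().shape[0] == 15

    def test_zero_variance_band_rejected(self):
        tcs = {"a": make_tc(canonical_series()), "b": make_tc(np.ones(1495))}
        with pytest.raises(ValueError):
            interval_correlations(tcs, "ISP2")

    def test_grid_invariant_to_common_affine_rescaling(self, rng):
        x, y = canonical_series(rng), canonical_series(rng)
        g1 = interval_correlations({"a": make_tc(x), "b": make_tc(y)}, "vowel")
        g2 = interval_correlations(
            {"a": make_tc(3.0 * x + 1.0), "b": make_tc(3.0 * y + 1.0)}, "vowel"
        )
        assert np.allclose(g1.r, g2.r, atol=1e-12)


class TestCvCenteredCorrelations:
    def test_window_centered_on_cv_boundary(self, rng):
        n = sum(canonical_grid(FS)[0])
        cv_idx = canonical_grid(FS)[1][1]
        # beta falls, gamma rises across the window: negative correlation
        ramp = np.linspace(-1, 1, n)
        tcs = {"beta_h": make_tc(-ramp), "hgamma_l": make_tc(ramp + 0.01 * rng.standard_normal(n))}
        grid = cv_centered_correlations(tcs, width=100)
        assert grid.interval == "cv_centered"
        assert grid.pair("beta_h", "hgamma_l")[0] < 0

    def test_co_rising_series_positively_correlated(self, rng):
        n = sum(canonical_grid(FS)[0])
        ramp = np.linspace(-1, 1, n)
        tcs = {
            "beta_h": make_tc(ramp + 0.01 * rng.standard_normal(n)),
            "hgamma_l": make_tc(2 * ramp + 0.01 * rng.standard_normal(n)),
        }
        grid = cv_centered_correlations(tcs, width=100)
        assert grid.pair("beta_h", "hgamma_l")[0] > 0

    def test_oversized_window_rejected(self):
        tcs = {"a": make_tc(canonical_series()), "b": make_tc(canonical_series())}
        with pytest.raises(ValueError):
            cv_centered_correlations(tcs, width=5000)

    def test_constant_window_rejected(self):
        n = sum(canonical_grid(FS)[0])
        tcs = {"a": make_tc(np.ones(n)), "b": make_tc(canonical_series())}
        with pytest.raises(ValueError):
            cv_centered_correlations(tcs, width=100)


class TestLocalExtrema:
    def test_single_bump_single_maximum(self):
        n = sum(canonical_grid(FS)[0])
        x = np.zeros(n)
        b1 = canonical_grid(FS)[1][0]
        apex = b1 // 2
        x[:b1] = -((np.arange(b1) - apex) ** 2)  # parabola peaking mid-ISP1
        ex = local_extrema(make_tc(x))
        assert ex.maxima["ISP1"].tolist() == [apex]
        assert ex.minima["ISP1"].size == 0

    def test_monotone_series_has_no_extrema(self):
        n = sum(canonical_grid(FS)[0])
        ex = local_extrema(make_tc(np.linspace(0, 1, n)))
        for interval in ("ISP1", "consonant", "vowel", "ISP2"):
            assert ex.maxima[interval].size == 0
            assert ex.minima[interval].size == 0

    def test_full_sine_period_one_max_one_min(self):
        n = sum(canonical_grid(FS)[0])
        b1 = canonical_grid(FS)[1][0]
        x = np.zeros(n)
        x[:b1] = np.sin(2 * np.pi * np.arange(b1) / b1)
        ex = local_extrema(make_tc(x))
        assert ex.maxima["ISP1"].size == 1
        assert ex.minima["ISP1"].size == 1


class TestWaveletMap:
    def test_constant_series_maps_to_zero(self):
        n = sum(canonical_grid(FS)[0])
        wm = gaussian_wavelet_map(make_tc(np.full(n, 5.0)))
        assert np.max(np.abs(wm.coefficients)) < 1e-9

    def test_gaussian_bump_matched_by_grid_search_oracle(self):
        """Map values equal a direct inner-product grid search, the peak
        sits at the bump centre, and wider bumps select wider templates."""
        n = sum(canonical_grid(FS)[0])
        t0 = 700

        def direct_coefficient(x, sigma, t):
            half = int(np.ceil(4 * sigma))
            u = np.arange(-half, half + 1)
            g = np.exp(-0.5 * (u / sigma) ** 2)
            g = (g - g.mean()) / np.linalg.norm(g - g.mean())
            return float(np.dot(x[t - half : t + half + 1], g))

        best_sigma = {}
        for s0 in (10, 25):
            x = np.exp(-0.5 * ((np.arange(n) - t0) / s0) ** 2)
            wm = gaussian_wavelet_map(make_tc(x))
            # interior values match the independent direct computation
            for sigma in (5, 15, 30):
                i = int(np.where(wm.sigmas == sigma)[0][0])
                for t in (500, t0, 900):
                    assert wm.coefficients[i, t] == pytest.approx(
                        direct_coefficient(x, sigma, t), abs=1e-9
                    )
            i, j = np.unravel_index(np.argmax(wm.coefficients), wm.coefficients.shape)
            assert abs(int(j) - t0) <= 2
            best_sigma[s0] = int(wm.sigmas[i])
        assert best_sigma[25] > best_sigma[10]

    def test_sign_flips_under_negation(self, rng):
        x = canonical_series(rng)
        a = gaussian_wavelet_map(make_tc(x)).coefficients
        b = gaussian_wavelet_map(make_tc(-x)).coefficients
        assert np.allclose(a, -b, atol=1e-10)

    def test_short_series_rejected(self):
        tc = BandPowerTimecourse(
            band="x", values=np.zeros(100), boundaries=(30, 40, 70),
            sample_rate_hz=FS,
        )
        with pytest.raises(ValueError):
            gaussian_wavelet_map(tc)


class TestMixedModelInference:
    def test_df_is_intervals_minus_one(self, rng):
        y = rng.standard_normal((8, 5))
        s = interval_lme_lrt(y)
        assert s.df == 4
        assert s.n_intervals == 5

    def test_effect_detected_and_recovered_within_3se(self, rng):
        truth = np.array([0.0, 0.0, 1.0, 1.0, 0.0])
        y = (
            0.5 * rng.standard_normal((31, 1))
            + rng.standard_normal((31, 5))
            + truth
        )
        s = interval_lme_lrt(y)
        assert s.p_value < 1e-3
        tk = tukey_pairwise(s)
        # contrast I1 vs I3 should recover the unit effect within 3 SE
        row = tk[(tk.interval_a == 1) & (tk.interval_b == 3)].iloc[0]
        assert abs(row.estimate - 1.0) < 3 * row.se

    def test_tukey_table_shape_and_probability_range(self, rng):
        s = interval_lme_lrt(rng.standard_normal((10, 4)))
        tk = tukey_pairwise(s)
        assert len(tk) == 6  # C(4,2)
        assert ((tk.p_tukey >= 0) & (tk.p_tukey <= 1)).all()

    def test_null_pairwise_significance_controlled(self):
        # equal interval means: family-wise share of significant pairs <= alpha
        rng = np.random.default_rng(777)
        sig = total = 0
        for _ in range(60):
            y = 0.5 * rng.standard_normal((31, 1)) + rng.standard_normal((31, 5))
            tk = tukey_pairwise(interval_lme_lrt(y))
            sig += int((tk.p_tukey < 0.05).sum())
            total += len(tk)
        assert sig / total <= 0.05

    def test_two_intervals_tukey_agrees_with_lrt(self, rng):
        clear = rng.standard_normal((20, 2)) + np.array([0.0, 2.0])
        s = interval_lme_lrt(clear)
        tk = tukey_pairwise(s)
        assert (s.p_value < 0.05) == bool(tk.p_tukey.iloc[0] < 0.05)
        null = rng.standard_normal((20, 2)) * 0.5 + 5.0
        s0 = interval_lme_lrt(null)
        tk0 = tukey_pairwise(s0)
        assert (s0.p_value < 0.05) == bool(tk0.p_tukey.iloc[0] < 0.05)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            interval_lme_lrt(np.zeros((1, 5)))
        with pytest.raises(ValueError):
            interval_lme_lrt(np.zeros((5, 1)))


class TestPreOnsetChangePoint:
    def test_last_change_point_before_onset(self):
        assert last_pre_onset_change_point(np.array([100, 480, 700]), 500) == 480
        assert last_pre_onset_change_point(np.array([600, 700]), 500) is None
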