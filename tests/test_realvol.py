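"""Realised-volatility estimation: detrending, T2* fit, weighting, variance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roughfmri.realvol import (
    MultiEchoSeries, RealisedVolSeries,
    detrend_linear, echo_weights, fit_t2star, framewise_displacement,
    log_floor_normalise, realised_variance, realised_vol_series,
    unweighted_variant, weighted_mean,
)

ECHOES_MS = np.array([12.0, 28.0, 44.0, 60.0])


class TestDetrend:
    def test_exact_line_gives_zero_residuals(self):
        t = np.arange(20.0)
        np.testing.assert_allclose(detrend_linear(3.0 + 0.7 * t),
                                   np.zeros(20), atol=1e-10)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        once = detrend_linear(x)
        np.testing.assert_allclose(detrend_linear(once), once, atol=1e-10)

    def test_quadratic_matches_normal_equations_oracle(self):
        # independent least-squares solve of t^2 on t = 1..10
        t = np.arange(1.0, 11.0)
        expected = [12.0, 4.0, -2.0, -6.0, -8.0, -8.0, -6.0, -2.0, 4.0, 12.0]
        np.testing.assert_allclose(detrend_linear(t ** 2), expected, atol=1e-9)

    def test_residual_moments(self):
        rng = np.random.default_rng(1)
        r = detrend_linear(rng.standard_normal(100))
        t = np.arange(100.0)
        assert abs(r.mean()) < 1e-10
        assert abs(np.cov(r, t)[0, 1]) < 1e-8

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detrend_linear(np.array([1.0, 2.0]))


class TestT2StarFit:
    def test_noiseless_decay_exact(self):
        s = 100.0 * np.exp(-ECHOES_MS / 50.0)
        fit = fit_t2star(s, ECHOES_MS)
        assert fit.valid
        assert fit.t2star_hat == pytest.approx(50.0, rel=1e-10)
        assert fit.s0_hat == pytest.approx(100.0, rel=1e-10)

    def test_constant_signal_invalid(self):
        fit = fit_t2star(np.full(4, 100.0), ECHOES_MS)
        assert not fit.valid

    def test_above_cap_invalid(self):
        s = 100.0 * np.exp(-ECHOES_MS / 1e4)
        assert not fit_t2star(s, ECHOES_MS).valid

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2)
        ests = []
        for _ in range(200):
            s = 100.0 * np.exp(-ECHOES_MS / 50.0) * (1 + 0.05 * rng.standard_normal(4))
            ests.append(fit_t2star(s, ECHOES_MS).t2star_hat)
        assert abs(np.median(ests) - 50.0) / 50.0 < 0.10

    def test_nonpositive_signal_raises(self):
        with pytest.raises(ValueError):
            fit_t2star(np.array([10.0, -1.0, 5.0, 2.0]), ECHOES_MS)


class TestEchoWeights:
    def test_equal_echo_times_uniform(self):
        w = echo_weights(np.full(5, 30.0), 40.0)
        np.testing.assert_allclose(w, 0.2)

    def test_infinite_t2star_proportional_to_echo_time(self):
        w = echo_weights(ECHOES_MS, 1e12)
        np.testing.assert_allclose(w, ECHOES_MS / ECHOES_MS.sum(), rtol=1e-6)

    def test_frozen_example(self):
        # direct high-precision evaluation of E_n exp(-E_n/30) normalised
        w = echo_weights(ECHOES_MS, 30.0)
        np.testing.assert_allclose(
            w, [0.21550697751875744, 0.29499482515862907,
                0.27194765549966543, 0.21755054182294806], rtol=1e-12)

    def test_nonpositive_t2star_raises(self):
        with pytest.raises(ValueError):
            echo_weights(ECHOES_MS, 0.0)


class TestWeightedMoments:
    def test_weighted_mean_trivia(self):
        assert weighted_mean(np.full(4, 3.3), np.ones(4) / 4) == pytest.approx(3.3)
        assert weighted_mean(np.array([5.0, 1.0]), np.array([1.0, 0.0])) == 5.0
        assert weighted_mean(np.array([4.0, 2.0]),
                             np.array([0.25, 0.75])) == pytest.approx(2.5)

    def test_weighted_mean_scale_invariance(self):
        y = np.array([1.0, 2.0, 7.0])
        w = np.array([0.2, 0.5, 0.3])
        assert weighted_mean(y, w) == pytest.approx(weighted_mean(y, 13.7 * w))

    def test_variance_trivia(self):
        assert realised_variance(np.full(4, 2.0), np.ones(4) / 4) == 0.0
        assert realised_variance(np.array([1.0, -1.0]),
                                 np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_variance_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.standard_normal(6)
            w = rng.uniform(0.1, 1.0, 6)
            ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
            expected = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y)) / sum(w)
            assert realised_variance(y, w) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10),
           seed=st.integers(0, 100))
    def test_location_invariance_and_quadratic_scaling(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(5)
        w = rng.uniform(0.1, 1.0, 5)
        base = realised_variance(y, w)
        assert realised_variance(y + shift, w) == pytest.approx(base, abs=1e-9)
        assert realised_variance(scale * y, w) == pytest.approx(
            scale ** 2 * base, rel=1e-9)

    def test_single_echo_raises(self):
        with pytest.raises(ValueError):
            realised_variance(np.array([1.0]), np.array([1.0]))


class TestSeriesPipeline:
    @staticmethod
    def _series(rng, T=60, decay=True):
        mu = 1000.0 * np.exp(-ECHOES_MS / 50.0) if decay else np.full(4, 1000.0)
        vals = mu[:, None] + rng.standard_normal((4, T))
        return MultiEchoSeries(vals, ECHOES_MS)

    def test_unweighted_equals_population_variance(self):
        rng = np.random.default_rng(4)
        s = self._series(rng)
        rv = unweighted_variant(s, detrend=False)
        expected = s.values.var(axis=0)  # denominator N
        np.testing.assert_allclose(rv.v_hat, expected, rtol=1e-10)
        assert not rv.weighted

    def test_weighted_equals_unweighted_for_equal_weights(self):
        rng = np.random.default_rng(5)
        s = self._series(rng)
        w = np.full(4, 0.25)
        y = s.values[:, 0]
        assert realised_variance(y, w) == pytest.approx(float(y.var()))

    def test_invalid_t2star_falls_back_with_warning(self):
        rng = np.random.default_rng(6)
        s = self._series(rng, decay=False)  # no decay -> invalid fit
        with pytest.warns(UserWarning, match="unweighted"):
            rv = realised_vol_series(s)
        assert not rv.weighted

    def test_vhat_tracks_latent_variance_better_with_more_echoes(self):
        # the realised-variance proxy correlates positively with the true
        # latent variance path, and more echoes mean a sharper estimate
        from roughfmri.rbergomi import RBergomiParams
        from roughfmri.synthetic import simulate_voxel_series
        echoes8 = (12., 28., 44., 60., 76., 92., 108., 124.)
        mean_corr = {}
        for n in (3, 8):
            cors = []
            for s in range(10):
                series, truth = simulate_voxel_series(
                    RBergomiParams(0.1, 1.5), echoes8[:n], 300, seed=100 + s)
                rv = unweighted_variant(series, detrend=False)
                cors.append(np.corrcoef(rv.v_hat, truth["v"])[0, 1])
            mean_corr[n] = np.mean(cors)
            assert all(c > 0 for c in cors)
        assert mean_corr[8] > mean_corr[3]

    def test_weighted_ranks_agree_with_unweighted(self):
        # the two pipelines should order voxels near-identically
        from scipy.stats import spearmanr
        rng = np.random.default_rng(7)
        vw, vu = [], []
        for _ in range(30):
            s = self._series(rng)
            vw.append(realised_vol_series(s).v_hat.mean())
            vu.append(unweighted_variant(s).v_hat.mean())
        assert spearmanr(vw, vu).statistic > 0.9


class TestLogFloorNormalise:
    def test_constant_series_maps_to_zero(self):
        rv = RealisedVolSeries(np.full(30, 4.0), weighted=True)
        np.testing.assert_allclose(log_floor_normalise(rv, 30), 0.0, atol=1e-12)

    def test_zero_entries_floored_finite(self):
        v = np.array([1.0, 0.0, 2.0, 1.5] * 10)
        path = log_floor_normalise(RealisedVolSeries(v, weighted=True), 40)
        assert np.all(np.isfinite(path))

    def test_truncation_to_target_length(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.5, 2.0, 239)
        rv = RealisedVolSeries(v, weighted=True)
        path = log_floor_normalise(rv, 200)
        assert len(path) == 200
        full = np.log(v[:200])
        np.testing.assert_allclose(path, full - full.mean(), atol=1e-10)

    def test_too_short_raises(self):
        rv = RealisedVolSeries(np.ones(10), weighted=True)
        with pytest.raises(ValueError):
            log_floor_normalise(rv, 11)

    def test_all_zero_series_raises(self):
        with pytest.raises(ValueError):
            RealisedVolSeries(np.zeros(10), weighted=True)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(np.zeros((10, 6)))
        np.testing.assert_array_equal(fd.fd, 0.0)

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 1.0  # 1 mm x step between frames 2 and 3
        fd = framewise_displacement(m)
        np.testing.assert_allclose(fd.fd, [0, 0, 1.0, 0, 0])

    def test_rotation_step_scaled_by_radius(self):
        m = np.zeros((4, 6))
        m[2:, 3] = 0.01  # 0.01 rad pitch step
        fd = framewise_displacement(m, radius_mm=50.0)
        assert fd.fd[2] == pytest.approx(0.5)

    def test_wrong_column_count_raises(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((10, 5)))
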