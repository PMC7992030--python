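"""Exactness of the rBergomi / fBm simulators and training-set construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from roughfmri.rbergomi import (
    LabelledPathSet, RBergomiParams, TimeGrid,
    cholesky_factor, covariance_matrix, fbm_covariance,
    rl_covariance, rl_covariance_quad,
    sample_training_set, simulate_fbm, simulate_logvol, split_nested,
    variance_process,
)


class TestCovariance:
    def test_brownian_case_is_min(self):
        s = np.array([0.1, 0.4, 0.9])
        t = np.array([0.7, 0.2, 0.9])
        np.testing.assert_allclose(rl_covariance(s, t, 0.5), np.minimum(s, t),
                                   rtol=1e-12)

    def test_variance_closed_form(self):
        # Var(vtilde_t)/eta^2 = t^2H / (2H)
        assert rl_covariance(1.0, 1.0, 0.25) == pytest.approx(2.0, rel=1e-12)
        for H in (0.05, 0.3, 0.9):
            t = 0.63
            assert rl_covariance(t, t, H) == pytest.approx(t ** (2 * H) / (2 * H),
                                                           rel=1e-10)

    @pytest.mark.parametrize("H,s,t", [
        (0.1, 0.3, 0.7), (0.05, 0.2, 1.0), (0.45, 0.5, 0.55), (0.8, 0.9, 0.1),
    ])
    def test_matches_adaptive_quadrature(self, H, s, t):
        closed = rl_covariance(s, t, H)
        quad = rl_covariance_quad(s, t, H)
        assert closed == pytest.approx(quad, abs=1e-8)

    def test_normalised_kernel_scales_by_2h(self):
        H = 0.2
        assert rl_covariance(1.0, 1.0, H, normalised_kernel=True) == \
            pytest.approx(1.0, rel=1e-10)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            rl_covariance(0.5, 0.5, 1.5)
        with pytest.raises(ValueError):
            rl_covariance(-0.1, 0.5, 0.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(H=st.floats(0.02, 0.98), s=st.floats(0.01, 1.0), t=st.floats(0.01, 1.0))
    def test_symmetry_and_diagonal(self, H, s, t):
        assert rl_covariance(s, t, H) == pytest.approx(rl_covariance(t, s, H),
                                                       rel=1e-10)
        assert rl_covariance(t, t, H) == pytest.approx(t ** (2 * H) / (2 * H),
                                                       rel=1e-8)


class TestCholesky:
    def test_scalar_grid(self):
        H = 0.3
        L = cholesky_factor(TimeGrid(1), H)
        assert L.shape == (1, 1)
        assert L[0, 0] == pytest.approx(np.sqrt(1.0 / (2 * H)), rel=1e-10)

    def test_two_point_brownian_closed_form(self):
        L = cholesky_factor(TimeGrid(2), 0.5)
        expected = np.array([[np.sqrt(0.5), 0.0], [np.sqrt(0.5), np.sqrt(0.5)]])
        np.testing.assert_allclose(L, expected, rtol=1e-10)

    @pytest.mark.parametrize("H", [0.05, 0.5, 0.9])
    def test_reconstruction_error(self, H):
        grid = TimeGrid(200)
        L = cholesky_factor(grid, H)
        C = covariance_matrix(grid, H)
        assert np.abs(L @ L.T - C).max() <= 1e-8 * np.abs(C).max()

    def test_caching_is_bit_identical(self):
        a = cholesky_factor(TimeGrid(50), 0.123)
        b = cholesky_factor(TimeGrid(50), 0.123)
        assert a is b or np.array_equal(a, b)


class TestSimulateLogvol:
    def test_zero_eta_gives_zero_paths(self):
        p = RBergomiParams(H=0.3, eta=0.0)
        paths = simulate_logvol(p, TimeGrid(20), 5, seed=0)
        assert np.all(paths == 0.0)

    def test_brownian_terminal_variance(self):
        p = RBergomiParams(H=0.5, eta=1.0)
        paths = simulate_logvol(p, TimeGrid(50), 10_000, seed=42)
        v = paths[:, -1].var()
        se = 1.0 * np.sqrt(2.0 / (10_000 - 1))
        assert abs(v - 1.0) < 3 * se

    def test_variance_matches_analytic_rough(self):
        p = RBergomiParams(H=0.1, eta=2.0)
        grid = TimeGrid(50)
        paths = simulate_logvol(p, grid, 10_000, seed=7)
        for i in (9, 24, 49):
            t = grid.t[i]
            ana = p.eta ** 2 * t ** (2 * p.H) / (2 * p.H)
            emp = paths[:, i].var()
            se = ana * np.sqrt(2.0 / (10_000 - 1))
            assert abs(emp - ana) < 3 * se

    def test_seed_reproducibility(self):
        p = RBergomiParams(H=0.2, eta=1.0)
        a = simulate_logvol(p, TimeGrid(10), 3, seed=5)
        b = simulate_logvol(p, TimeGrid(10), 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_small_grid_joint_covariance(self):
        # exactness invariant: sample covariance on a tiny grid matches the
        # analytic kernel entrywise within Monte-Carlo tolerance
        p = RBergomiParams(H=0.15, eta=1.0)
        grid = TimeGrid(4)
        paths = simulate_logvol(p, grid, 100_000, seed=11)
        emp = np.cov(paths, rowvar=False)
        ana = covariance_matrix(grid, p.H)
        assert np.abs(emp - ana).max() < 0.03 * np.abs(ana).max()


class TestVarianceProcess:
    def test_zero_eta_constant(self):
        p = RBergomiParams(H=0.3, eta=0.0, xi0=2.5)
        v = variance_process(np.zeros((3, 10)), p, TimeGrid(10))
        np.testing.assert_allclose(v, 2.5)

    def test_xi0_linearity(self):
        grid = TimeGrid(10)
        logvol = simulate_logvol(RBergomiParams(0.3, 1.0), grid, 2, seed=1)
        v1 = variance_process(logvol, RBergomiParams(0.3, 1.0, xi0=1.0), grid)
        v2 = variance_process(logvol, RBergomiParams(0.3, 1.0, xi0=2.0), grid)
        np.testing.assert_allclose(v2, 2.0 * v1, rtol=1e-12)

    def test_mean_is_xi0_with_normalised_kernel(self):
        # with the sqrt(2H)-normalised kernel the compensator exactly offsets
        # the log-normal mean, so E[v_t] = xi0
        p = RBergomiParams(H=0.3, eta=1.0, xi0=1.0)
        grid = TimeGrid(20)
        logvol = simulate_logvol(p, grid, 50_000, seed=3, normalised_kernel=True)
        v = variance_process(logvol, p, grid)
        t = grid.t[-1]
        mean_emp = v[:, -1].mean()
        var_v = np.exp(2 * p.eta ** 2 * t ** (2 * p.H)) - np.exp(p.eta ** 2 * t ** (2 * p.H))
        se = np.sqrt(var_v / 50_000)
        assert abs(mean_emp - 1.0) < 4 * se

    def test_positivity(self):
        p = RBergomiParams(H=0.1, eta=3.0)
        grid = TimeGrid(30)
        v = variance_process(simulate_logvol(p, grid, 100, seed=9), p, grid)
        assert np.all(v > 0)


class TestFBM:
    def test_brownian_increments_iid_normal(self):
        grid = TimeGrid(100)
        paths = simulate_fbm(0.5, grid, 500, seed=21)
        inc = np.diff(np.concatenate([np.zeros((500, 1)), paths], axis=1), axis=1)
        z = inc.ravel() / np.sqrt(1.0 / 100)
        assert stats.normaltest(z).pvalue > 0.01
        assert abs(z.var() - 1.0) < 3 * np.sqrt(2.0 / len(z))

    @pytest.mark.parametrize("H", [0.1, 0.5, 0.9])
    def test_terminal_variance(self, H):
        paths = simulate_fbm(H, TimeGrid(50), 10_000, seed=33)
        ana = 1.0  # t = 1 -> t^2H = 1
        emp = paths[:, -1].var()
        assert abs(emp - ana) < 3 * ana * np.sqrt(2.0 / (10_000 - 1))

    def test_self_similarity_ratio(self):
        H = 0.3
        grid = TimeGrid(100)
        paths = simulate_fbm(H, grid, 20_000, seed=44)
        # Var(B_2t)/Var(B_t) = 2^2H at t = 0.5 vs t = 1.0
        ratio = paths[:, 99].var() / paths[:, 49].var()
        ana = 2.0 ** (2 * H)
        assert ratio == pytest.approx(ana, rel=0.1)

    def test_roughness_ordering(self):
        # mean absolute increment at fixed dt decreases in H
        grid = TimeGrid(100)
        mai = []
        for H in (0.1, 0.5, 0.9):
            paths = simulate_fbm(H, grid, 500, seed=55)
            mai.append(np.abs(np.diff(paths, axis=1)).mean())
        assert mai[0] > mai[1] > mai[2]


class TestTrainingSet:
    def test_unique_pairs_and_ranges(self):
        ps = sample_training_set(2000, TimeGrid(25), seed=1)
        pairs = np.column_stack([ps.H, ps.eta])
        assert len(np.unique(pairs, axis=0)) == 2000
        assert np.all((ps.H > 0) & (ps.H < 1))
        labels = ps.labels
        assert np.all((labels[:, 1] > 0) & (labels[:, 1] < np.tanh(3.0)))

    def test_h_mean_matches_uniform(self):
        ps = sample_training_set(10_000, TimeGrid(10), seed=2)
        se = (1.0 / np.sqrt(12.0)) / np.sqrt(10_000)
        assert abs(ps.H.mean() - 0.5) < 3 * se

    def test_path_law_consistent_with_labels(self):
        # all paths share the grid; per-path std at t=1 grows with eta
        ps = sample_training_set(500, TimeGrid(25), seed=3)
        big = ps.eta > 2.0
        small = ps.eta < 0.5
        assert np.abs(ps.paths[big, -1]).mean() > np.abs(ps.paths[small, -1]).mean()

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            sample_training_set(5, TimeGrid(10), seed=0)
        with pytest.raises(ValueError):
            sample_training_set(100, TimeGrid(10), H_range=(0.5, 0.5), seed=0)


class TestSplitNested:
    @staticmethod
    def _dummy(P):
        return LabelledPathSet(np.zeros((P, 2), dtype=np.float32),
                               np.linspace(0.01, 0.99, P),
                               np.linspace(0.01, 2.99, P), TimeGrid(2))

    def test_full_scale_split_arithmetic(self):
        ps = split_nested(self._dummy(50_000), seed=0)
        counts = {t: int((ps.partition == t).sum())
                  for t in ("train", "val", "test")}
        assert counts == {"train": 28_000, "val": 7_000, "test": 15_000}

    def test_small_p_rounding(self):
        ps = split_nested(self._dummy(10), seed=0)
        counts = {t: int((ps.partition == t).sum())
                  for t in ("train", "val", "test")}
        assert counts == {"train": 6, "val": 1, "test": 3}

    def test_determinism_and_exhaustiveness(self):
        a = split_nested(self._dummy(100), seed=9).partition
        b = split_nested(self._dummy(100), seed=9).partition
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) == {"train", "val", "test"}

    def test_save_load_roundtrip(self, tmp_path):
        ps = split_nested(self._dummy(20), seed=1)
        f = tmp_path / "paths.npz"
        ps.save(f)
        back = LabelledPathSet.load(f)
        np.testing.assert_array_equal(back.paths, ps.paths)
        np.testing.assert_array_equal(back.partition, ps.partition)
        assert back.grid.M == ps.grid.M
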