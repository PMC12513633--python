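"""Circadian damped-oscillator generator: closed forms and noise structure."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

from endnsde import circadian as circ


class TestDiffusionMatrix:
    def test_const_form(self):
        p = circ.CircadianParams(diffusion_form="const", sigma0=0.1, c=0.2)
        assert np.allclose(circ.diffusion_matrix(p, 5.0, -3.0),
                           [[0.1, 0.02], [0.02, 0.1]])

    def test_langevin_vanishes_at_origin(self):
        p = circ.CircadianParams(diffusion_form="langevin", sigma0=0.3, c=0.5)
        assert np.allclose(circ.diffusion_matrix(p, 0.0, 0.0), np.zeros((2, 2)))

    def test_linear_sign_asymmetry(self):
        """Diagonal keeps the sign of x and y; off-diagonal uses |x|, |y|."""
        p = circ.CircadianParams(diffusion_form="linear", sigma0=1.0, c=1.0)
        assert np.allclose(circ.diffusion_matrix(p, -1.0, 1.0),
                           [[-1.0, 1.0], [1.0, 1.0]])

    def test_percell_routed_to_own_field(self):
        p = circ.CircadianParams(diffusion_form="percell")
        with pytest.raises(ValueError):
            circ.diffusion_matrix(p, 0.0, 0.0)


class TestSimulate:
    def test_noise_free_closed_form(self):
        """sigma0 = 0 from (0,1): x = -e^{-at} sin(bt), y = e^{-at} cos(bt)."""
        times = np.linspace(0, 1, 201)
        ens = circ.simulate(circ.CircadianParams(sigma0=0.0), (0, 1), times, 2, seed=0)
        a, b = circ.DEFAULT_ALPHA, circ.DEFAULT_BETA
        x_exact = -np.exp(-a * times) * np.sin(b * times)
        y_exact = np.exp(-a * times) * np.cos(b * times)
        assert np.abs(ens.values[0, :, 0] - x_exact).max() < 5e-4
        assert np.abs(ens.values[0, :, 1] - y_exact).max() < 5e-4

    def test_one_step_covariance_matches_diffusion_matrix(self):
        """E[dX dX^T] / dt at a frozen state equals (xi xi^T) for each form."""
        state = (0.6, -0.8)
        dt = 1e-3
        for form in ("const", "langevin", "linear"):
            p = circ.CircadianParams(diffusion_form=form, sigma0=0.25, c=0.5)
            ens = circ.simulate(p, state, np.array([0.0, dt]), 60000, seed=42)
            dx = ens.values[:, 1, :] - ens.values[:, 0, :]
            dx -= dx.mean(axis=0)
            emp = dx.T @ dx / dx.shape[0] / dt
            xi = circ.diffusion_matrix(p, *state)
            assert np.allclose(emp, xi @ xi.T, atol=0.02), form

    def test_stationary_covariance_lyapunov_oracle(self):
        """Long-run covariance of the const-diffusion linear SDE solves
        A P + P A^T + S S^T = 0."""
        a, b = circ.DEFAULT_ALPHA, circ.DEFAULT_BETA
        p = circ.CircadianParams(diffusion_form="const", sigma0=0.2, c=0.4)
        A = np.array([[-a, -b], [b, -a]])
        S = circ.diffusion_matrix(p, 0, 0)
        P = solve_continuous_lyapunov(A, -S @ S.T)
        times = np.linspace(0, 40, 1001)
        ens = circ.simulate(p, (0, 1), times, 800, seed=5)
        emp = np.cov(ens.values[:, -1, :].T)
        assert np.allclose(emp, P, rtol=0.2, atol=0.01)

    def test_percell_effective_coefficients(self):
        """(k1,k2)=(1,1) at sigma0=sigma1=0.1: diagonal diffusion 0.2x, 0.2y."""
        fld = circ.field_for_form("percell", sigma0=0.1, sigma1=0.1)
        states = np.array([[0.5, -0.4]])
        g = fld.diffusion(states, np.array([1.0, 1.0]))
        assert np.allclose(g[0], [[0.2 * 0.5, 0.0], [0.0, 0.2 * -0.4]])


class TestDatasets:
    def test_grid_values_and_counts(self):
        grid = circ.make_grid_dataset("const", seed=0, n_traj=4)
        omegas = np.array(grid.omegas())
        assert sorted(set(omegas[:, 0])) == pytest.approx([0.10, 0.15, 0.20, 0.25, 0.30])
        assert sorted(set(omegas[:, 1])) == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])
        assert len(grid.entries) == 25
        assert grid.n_traj_total == 100
        for e in grid.entries:
            assert np.allclose(e.ensemble.values[:, 0, :], [0.0, 1.0])

    def test_two_seeds_same_grid_different_paths(self):
        g1 = circ.make_grid_dataset("const", seed=1, n_traj=3)
        g2 = circ.make_grid_dataset("const", seed=2, n_traj=3)
        assert g1.omegas() == g2.omegas()
        assert not np.allclose(g1.entries[0].ensemble.values,
                               g2.entries[0].ensemble.values)

    def test_percell_grid(self):
        grid = circ.make_percell_dataset(0.1, 0.05, seed=0, n_traj=2)
        keys = set(grid.omegas())
        assert keys == {(k1, k2) for k1 in (-1, -0.5, 0, 0.5, 1)
                        for k2 in (-1, -0.5, 0, 0.5, 1)}
        assert grid.metadata["sigma0"] == 0.1
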