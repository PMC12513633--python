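"""Euler--Maruyama integrator and the neural-SDE training loop."""

import numpy as np
import pytest

from endnsde.data import ExtrinsicParamGrid, GridEntry, RunConfig, TrajectoryEnsemble
from endnsde.model import (EndNSDE, NeuralSDEField, SDEField, em_integrate,
                           load_results)


def _field(drift, diffusion, d=1, p=1, m=1):
    return SDEField(state_dim=d, param_dim=p, noise_dim=m,
                    drift=drift, diffusion=diffusion)


def _const_field(alpha=0.0, sigma=0.0):
    return _field(lambda x, om: -alpha * x,
                  lambda x, om: np.full((x.shape[0], 1, 1), sigma))


class TestEMIntegrate:
    def test_exponential_decay_and_step_halving(self):
        """Noise-free dx = -alpha x dt matches e^{-alpha t}; the global
        error is O(dt): it roughly halves when dt halves."""
        alpha = 0.19
        f = _const_field(alpha=alpha)
        errs = []
        for n_steps in (50, 100):
            times = np.linspace(0, 1, n_steps + 1)
            ens = em_integrate(f, np.array([1.0]), np.array([0.0]), times, 1, seed=0)
            errs.append(abs(ens.values[0, -1, 0] - np.exp(-alpha)))
        assert errs[0] < 2e-3
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.2)

    def test_zero_field_constant(self):
        ens = em_integrate(_const_field(), np.array([2.5]), np.array([0.0]),
                           np.linspace(0, 1, 11), 4, seed=1)
        assert np.all(ens.values == 2.5)

    def test_brownian_variance_growth(self):
        """Zero drift, constant sigma: Var X(T) ~ sigma^2 T."""
        sigma = 0.7
        ens = em_integrate(_const_field(sigma=sigma), np.array([0.0]),
                           np.array([0.0]), np.linspace(0, 2, 41), 4000, seed=2)
        v = ens.values[:, -1, 0].var()
        assert v == pytest.approx(sigma**2 * 2.0, rel=0.1)

    def test_deterministic_for_fixed_seed(self):
        f = _const_field(alpha=0.5, sigma=0.3)
        a = em_integrate(f, np.array([1.0]), np.array([0.0]),
                         np.linspace(0, 1, 11), 5, seed=9)
        b = em_integrate(f, np.array([1.0]), np.array([0.0]),
                         np.linspace(0, 1, 11), 5, seed=9)
        c = em_integrate(f, np.array([1.0]), np.array([0.0]),
                         np.linspace(0, 1, 11), 5, seed=10)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_overflow_reports_step(self):
        exploding = _field(lambda x, om: 10.0 * x**2,
                           lambda x, om: np.zeros((x.shape[0], 1, 1)))
        with pytest.raises(FloatingPointError, match="step"):
            em_integrate(exploding, np.array([5.0]), np.array([0.0]),
                         np.linspace(0, 5, 200), 1, seed=0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            em_integrate(_const_field(), np.array([1.0, 2.0]), np.array([0.0]),
                         np.linspace(0, 1, 5), 1, seed=0)


def _ou_grid(theta=1.0, s=0.3, n_traj=200, seed=0):
    fld = _field(lambda x, om: -theta * x,
                 lambda x, om: np.full((x.shape[0], 1, 1), s))
    ens = em_integrate(fld, np.array([1.0]), np.array([0.0]),
                       np.linspace(0, 1, 51), n_traj, seed=seed)
    return ExtrinsicParamGrid(entries=[GridEntry(ens.omega, ens, "train")])


class TestTraining:
    def test_final_loss_below_initial(self):
        grid = _ou_grid(n_traj=100)
        res = EndNSDE(grid, RunConfig(seed=1, imax=30, hidden=(16, 16), lr=3e-3)).fit()
        assert res.loss_history[-1] < res.loss_history[0]

    def test_training_deterministic_for_seed(self):
        grid = _ou_grid(n_traj=40)
        cfg = RunConfig(seed=4, imax=5, hidden=(8,), lr=1e-3)
        a = EndNSDE(grid, cfg).fit()
        b = EndNSDE(grid, cfg).fit()
        assert a.loss_history == b.loss_history
        for pa, pb in zip(a.field.params, b.field.params):
            assert np.array_equal(pa, pb)

    def test_predict_deterministic_and_tags_heldout(self):
        grid = _ou_grid(n_traj=30)
        res = EndNSDE(grid, RunConfig(seed=2, imax=3, hidden=(8,))).fit()
        t = np.linspace(0, 1, 11)
        a = res.predict(np.array([1.0]), np.array([0.5]), t, 3, seed=5)
        b = res.predict(np.array([1.0]), np.array([0.5]), t, 3, seed=5)
        assert np.array_equal(a.values, b.values)
        assert a.metadata["omega_seen_in_training"] is False
        c = res.predict(np.array([1.0]), np.array([0.0]), t, 1, seed=5)
        assert c.metadata["omega_seen_in_training"] is True
        assert c.n_traj == 1

    def test_empty_grid_rejected(self, small_ensemble):
        grid = ExtrinsicParamGrid(entries=[
            GridEntry(small_ensemble.omega, small_ensemble, "test")])
        with pytest.raises(ValueError, match="no training"):
            EndNSDE(grid, RunConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        grid = _ou_grid(n_traj=30)
        res = EndNSDE(grid, RunConfig(seed=3, imax=4, hidden=(8,))).fit()
        res.save(tmp_path / "model.h5")
        back = load_results(tmp_path / "model.h5")
        t = np.linspace(0, 1, 6)
        a = res.predict(np.array([1.0]), np.array([0.0]), t, 4, seed=1)
        b = back.predict(np.array([1.0]), np.array([0.0]), t, 4, seed=1)
        assert np.allclose(a.values, b.values)
        assert back.loss_history == pytest.approx(res.loss_history)


def test_neural_field_shapes_and_finiteness(rng):
    f = NeuralSDEField(state_dim=3, param_dim=2, noise_dim=2, hidden=(8, 8), rng=rng)
    x = rng.normal(size=(5, 3)) * 100
    om = rng.normal(size=2)
    assert f.drift(x, om).shape == (5, 3)
    g = f.diffusion(x, om)
    assert g.shape == (5, 3, 2)
    assert np.all(np.isfinite(f.drift(x, om))) and np.all(np.isfinite(g))
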