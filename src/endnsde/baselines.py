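"""Comparator time-series models scored by the same W2 machinery.

Four families: a vanilla recurrent network and an LSTM (sequence models
trained as teacher-forced next-increment predictors and rolled out
autoregressively), a neural ODE (a deterministic learned vector field,
trained with the same W2 objective as the SDE but with the diffusion
frozen at zero), and a Gaussian-process regressor of the state on the
extrinsic parameter, fitted per time point and state component, whose
posterior-predictive draws provide the prediction ensembles.

Every family exposes the same ``predict(x0, omega, times, n_traj, seed)``
contract as the fitted neural SDE so evaluation code is family-agnostic,
and every family is scored by the identical extrinsic-noise-driven W2
loss — there is no per-family metric code.

Recurrent hidden widths default to values that match the neural SDE's
parameter count within a factor of two (fair-comparison convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import ExtrinsicParamGrid, GridEntry, RunConfig, TrajectoryEnsemble, substream
from .model import EndNSDE, EndNSDEResults
from .nn import Adam
from .wasserstein import extrinsic_loss

__all__ = ["train_baseline", "benchmark", "RecurrentBaseline", "GPBaseline",
           "NeuralODEBaseline", "FAMILIES"]

FAMILIES = ("rnn", "lstm", "node", "gp")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _training_arrays(grid: ExtrinsicParamGrid):
    """Stack all training ensembles into (X, omega_rows, times)."""
    entries = [e for e in grid.entries if e.split == "train"]
    if not entries:
        raise ValueError("grid contains no training ensembles")
    times = entries[0].ensemble.times
    for e in entries:
        if not np.allclose(e.ensemble.times, times):
            raise ValueError("recurrent baselines require a common time grid")
    X = np.concatenate([e.ensemble.values for e in entries])
    om = np.concatenate([
        np.broadcast_to(e.omega, (e.ensemble.n_traj, e.omega.size)) for e in entries])
    return X, om, times


class RecurrentBaseline:
    """Vanilla RNN or LSTM next-increment predictor conditioned on omega.

    The network consumes (state, omega) at each step, updates its hidden
    state and emits the state increment to the next grid time.  Rollouts
    are deterministic given (x0, omega): the predicted per-time marginals
    are point masses.
    """

    def __init__(self, family: str, state_dim: int, param_dim: int,
                 hidden: int, rng: np.random.Generator) -> None:
        if family not in ("rnn", "lstm"):
            raise ValueError(family)
        self.family = family
        self.state_dim = state_dim
        self.param_dim = param_dim
        self.hidden = hidden
        in_dim = state_dim + param_dim
        gate = 4 * hidden if family == "lstm" else hidden
        s_in = 1.0 / np.sqrt(in_dim)
        s_h = 1.0 / np.sqrt(hidden)
        self.W = rng.normal(0, s_in, size=(in_dim, gate))
        self.U = rng.normal(0, s_h, size=(hidden, gate))
        self.b = np.zeros(gate)
        if family == "lstm":
            self.b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.Wo = rng.normal(0, 0.1 * s_h, size=(hidden, state_dim))
        self.bo = np.zeros(state_dim)

    @property
    def params(self) -> List[np.ndarray]:
        return [self.W, self.U, self.b, self.Wo, self.bo]

    # ---- forward over a whole batch of sequences ------------------------
    def _forward(self, X: np.ndarray, om: np.ndarray, store: bool):
        N, T, d = X.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        preds = np.empty((N, T - 1, d))
        cache = []
        for t in range(T - 1):
            inp = np.concatenate([X[:, t], om], axis=1)
            z = inp @ self.W + h @ self.U + self.b
            if self.family == "lstm":
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                o = _sigmoid(z[:, 2 * H:3 * H])
                g = np.tanh(z[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if store:
                    cache.append((inp, h, c, i, f, o, g, tc))
                c = c_new
            else:
                h_new = np.tanh(z)
                if store:
                    cache.append((inp, h, h_new))
            h = h_new
            preds[:, t] = h @ self.Wo + self.bo
        return preds, cache

    def _backward(self, X, om, cache, dpreds):
        N, T, d = X.shape
        H = self.hidden
        grads = [np.zeros_like(p) for p in self.params]
        gW, gU, gb, gWo, gbo = grads
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 2, -1, -1):
            dp = dpreds[:, t]
            if self.family == "lstm":
                inp, h_prev, c_prev, i, f, o, g, tc = cache[t]
                h_t_grad = dp @ self.Wo.T + dh_next
                gWo += (o * tc).T @ dp
                gbo += dp.sum(axis=0)
                do = h_t_grad * tc
                dc = h_t_grad * o * (1 - tc**2) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate([
                    di * i * (1 - i), df * f * (1 - f),
                    do * o * (1 - o), dg * (1 - g**2)], axis=1)
                dc_next = dc * f
            else:
                inp, h_prev, h_t = cache[t]
                h_t_grad = dp @ self.Wo.T + dh_next
                gWo += h_t.T @ dp
                gbo += dp.sum(axis=0)
                dz = h_t_grad * (1 - h_t**2)
            gW += inp.T @ dz
            gU += cache[t][1].T @ dz
            gb += dz.sum(axis=0)
            dh_next = dz @ self.U.T
        return grads

    def fit(self, grid: ExtrinsicParamGrid, config: RunConfig,
            verbose: bool = False) -> "RecurrentBaseline":
        X, om, times = _training_arrays(grid)
        targets = np.diff(X, axis=1)
        opt = Adam(self.params, lr=config.lr)
        self.loss_history = []
        for epoch in range(config.imax):
            preds, cache = self._forward(X, om, store=True)
            err = preds - targets
            loss = float(np.mean(err**2))
            dpreds = 2.0 * err / err.size
            grads = self._backward(X, om, cache, dpreds)
            opt.step(grads)
            self.loss_history.append(loss)
            if verbose and epoch % 50 == 0:
                print(f"{self.family} epoch {epoch} mse {loss:.3e}")
        self.times = times
        return self

    def predict(self, x0, omega, times, n_traj: int, seed: int) -> TrajectoryEnsemble:
        times = np.asarray(times, dtype=float).ravel()
        x0 = np.asarray(x0, dtype=float)
        if x0.ndim == 1:
            x0 = np.broadcast_to(x0, (n_traj, x0.size)).copy()
        N, d = x0.shape
        om = np.broadcast_to(np.atleast_1d(omega), (N, np.atleast_1d(omega).size))
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        out = np.empty((N, times.size, d))
        out[:, 0] = x0
        x = x0
        for t in range(times.size - 1):
            inp = np.concatenate([x, om], axis=1)
            z = inp @ self.W + h @ self.U + self.b
            if self.family == "lstm":
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                o = _sigmoid(z[:, 2 * H:3 * H])
                g = np.tanh(z[:, 3 * H:])
                c = f * c + i * g
                h = o * np.tanh(c)
            else:
                h = np.tanh(z)
            x = x + h @ self.Wo + self.bo
            out[:, t + 1] = x
        return TrajectoryEnsemble(times=times, values=out,
                                  omega=np.atleast_1d(omega),
                                  metadata={"family": self.family, "seed": int(seed)})


class NeuralODEBaseline:
    """Deterministic learned vector field, trained with the W2 objective
    but with the diffusion frozen at zero (shares the SDE trainer)."""

    family = "node"

    def __init__(self, results: EndNSDEResults) -> None:
        self.results = results

    def predict(self, x0, omega, times, n_traj: int, seed: int) -> TrajectoryEnsemble:
        return self.results.predict(x0, omega, times, n_traj, seed)


class GPBaseline:
    """Per-time, per-component Gaussian-process regression of the state on
    the extrinsic parameter.

    Kernel: constant * RBF + white noise on standardized omega inputs; the
    white-noise level absorbs the trajectory-to-trajectory dispersion, so
    posterior-predictive draws (the prediction "ensemble") reproduce both
    the conditional mean and the spread.  Hyperparameters are optimized
    independently at every (time, component); a (time, component) whose
    response is constant across the data gets a degenerate point
    predictor.
    """

    family = "gp"

    def __init__(self, max_per_omega: int = 20) -> None:
        self.max_per_omega = max_per_omega

    def fit(self, grid: ExtrinsicParamGrid, config: RunConfig) -> "GPBaseline":
        import warnings

        from sklearn.exceptions import ConvergenceWarning
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        entries = [e for e in grid.entries if e.split == "train"]
        times = entries[0].ensemble.times
        rng = np.random.default_rng(substream(config.seed, "gp-subsample"))
        omegas, values = [], []
        for e in entries:
            n = min(self.max_per_omega, e.ensemble.n_traj)
            rows = np.sort(rng.choice(e.ensemble.n_traj, size=n, replace=False))
            values.append(e.ensemble.values[rows])
            omegas.append(np.broadcast_to(e.omega, (n, e.omega.size)))
        V = np.concatenate(values)            # (Ns, T, d)
        OM = np.concatenate(omegas)           # (Ns, p)
        self._om_mu = OM.mean(axis=0)
        self._om_sd = OM.std(axis=0) + 1e-12
        OMs = (OM - self._om_mu) / self._om_sd
        T, d = V.shape[1], V.shape[2]
        self.times = times
        self.state_dim = d
        self._gps: Dict[Tuple[int, int], object] = {}
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=1.0, length_scale_bounds=(0.05, 50.0))
                  + WhiteKernel(0.25, (1e-8, 2.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for k in range(d):
                for t in range(T):
                    y = V[:, t, k]
                    if y.std() < 1e-10:
                        self._gps[(t, k)] = ("const", float(y.mean()))
                        continue
                    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                                  alpha=1e-10)
                    gp.fit(OMs, y)
                    self._gps[(t, k)] = ("gp", gp)
        return self

    def predict(self, x0, omega, times, n_traj: int, seed: int) -> TrajectoryEnsemble:
        times = np.asarray(times, dtype=float).ravel()
        if times.size != self.times.size or not np.allclose(times, self.times):
            raise ValueError("GP baseline can only predict on its training grid")
        rng = np.random.default_rng(seed)
        om = np.atleast_2d(np.atleast_1d(omega))
        oms = (om - self._om_mu) / self._om_sd
        out = np.empty((n_traj, times.size, self.state_dim))
        for t in range(times.size):
            for k in range(self.state_dim):
                kind, obj = self._gps[(t, k)]
                if kind == "const":
                    out[:, t, k] = obj
                else:
                    mean, std = obj.predict(oms, return_std=True)
                    out[:, t, k] = mean[0] + std[0] * rng.standard_normal(n_traj)
        x0 = np.asarray(x0, dtype=float)
        return TrajectoryEnsemble(times=times, values=out,
                                  omega=np.atleast_1d(omega),
                                  metadata={"family": "gp", "seed": int(seed)})


def train_baseline(family: str, grid: ExtrinsicParamGrid, config: RunConfig,
                   verbose: bool = False):
    """Fit one comparator family on the training entries of ``grid``."""
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    X, om, _ = _training_arrays(grid)
    d, p = X.shape[2], om.shape[1]
    rng = np.random.default_rng(substream(config.seed, f"baseline:{family}"))
    if family in ("rnn", "lstm"):
        hidden = int(config.extra.get("recurrent_hidden",
                                      64 if family == "rnn" else 32))
        return RecurrentBaseline(family, d, p, hidden, rng).fit(
            grid, config, verbose=verbose)
    if family == "node":
        from dataclasses import replace
        node_cfg = replace(config, zero_diffusion=True)
        return NeuralODEBaseline(EndNSDE(grid, node_cfg).fit(verbose=verbose))
    return GPBaseline().fit(grid, config)


def benchmark(models: Dict[str, object], test_grid: ExtrinsicParamGrid,
              seed: int = 0) -> pd.DataFrame:
    """Score every model on the test entries with the extrinsic-noise W2 loss.

    Each model simulates a matched-size ensemble from every test ensemble's
    initial states; the table reports the summed loss over the test omega
    set, sorted ascending (best first).
    """
    entries = [e for e in test_grid.entries if e.split == "test"] or test_grid.entries
    ref = ExtrinsicParamGrid(entries=[GridEntry(e.omega, e.ensemble, "test")
                                      for e in entries])
    rows = []
    for name, model in models.items():
        pred_entries = []
        for i, e in enumerate(entries):
            ens = e.ensemble
            pred = model.predict(ens.initial_states(), e.omega, ens.times,
                                 ens.n_traj, substream(seed, f"bench:{name}:{i}"))
            pred_entries.append(GridEntry(e.omega, pred, "test"))
        report = extrinsic_loss(ref, ExtrinsicParamGrid(entries=pred_entries))
        rows.append({"model": name, "loss": report.total})
    return pd.DataFrame(rows).sort_values("loss").reset_index(drop=True)
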