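"""Parameter-conditioned neural SDE reconstruction (model / results objects).

The model learns a family of SDEs

    dX = f(X; omega) dt + sigma(X; omega) dB_t

from ensembles of trajectories observed at different extrinsic-parameter
values omega.  Drift and diffusion are separate multilayer perceptrons that
take the state and omega concatenated as input.  Training simulates the
candidate SDE from the observed initial states with Euler--Maruyama,
scores the simulated ensembles against the observed ones with the
extrinsic-noise-driven temporally decoupled squared W2 loss, and
backpropagates through the full integration unroll.

The public surface follows the model/results convention: ``EndNSDE(grid,
config).fit()`` returns an :class:`EndNSDEResults` carrying the learned
field, the loss history, ``predict`` and ``summary``.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import (ExtrinsicParamGrid, GridEntry, RunConfig, TrajectoryEnsemble,
                   substream)
from .nn import MLP, Adam, global_norm_clip
from .wasserstein import LossReport, quadrature_weights

__all__ = ["SDEField", "NeuralSDEField", "EndNSDE", "EndNSDEResults", "em_integrate"]


@dataclass
class SDEField:
    """A parameter-conditioned pair (drift, diffusion).

    ``drift(X, omega) -> (n, d)`` and ``diffusion(X, omega) -> (n, d, m)``
    with ``X`` of shape (n, d) and ``omega`` either a single vector or one
    row per sample.  ``latent_mask`` lists the state components that enter
    the training loss; components outside it evolve but are never scored.
    """

    state_dim: int
    param_dim: int
    noise_dim: int
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    diffusion: Callable[[np.ndarray, np.ndarray], np.ndarray]
    latent_mask: Optional[Tuple[int, ...]] = None


def _broadcast_omega(omega: np.ndarray, n: int) -> np.ndarray:
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    if om.ndim == 1:
        return np.broadcast_to(om, (n, om.size))
    if om.shape[0] != n:
        raise ValueError(f"omega rows ({om.shape[0]}) != number of samples ({n})")
    return om


class NeuralSDEField(SDEField):
    """SDE field whose drift and diffusion are MLPs over (X, omega)."""

    def __init__(self, state_dim: int, param_dim: int, noise_dim: int,
                 hidden: Sequence[int], rng: np.random.Generator,
                 drift_out_scale: float = 0.1, diffusion_out_scale: float = 0.05,
                 latent_mask: Optional[Tuple[int, ...]] = None,
                 zero_diffusion: bool = False) -> None:
        in_dim = state_dim + param_dim
        self.drift_net = MLP((in_dim, *hidden, state_dim), rng, out_scale=drift_out_scale)
        self.diffusion_net = None if zero_diffusion else MLP(
            (in_dim, *hidden, state_dim * noise_dim), rng, out_scale=diffusion_out_scale)
        self.zero_diffusion = zero_diffusion
        super().__init__(
            state_dim=state_dim, param_dim=param_dim, noise_dim=noise_dim,
            drift=self._drift, diffusion=self._diffusion, latent_mask=latent_mask)

    def _inputs(self, x: np.ndarray, omega: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        om = _broadcast_omega(omega, x.shape[0])
        return np.concatenate([x, om], axis=1)

    def _drift(self, x: np.ndarray, omega: np.ndarray) -> np.ndarray:
        return self.drift_net.value(self._inputs(x, omega))

    def _diffusion(self, x: np.ndarray, omega: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.zero_diffusion:
            return np.zeros((x.shape[0], self.state_dim, self.noise_dim))
        flat = self.diffusion_net.value(self._inputs(x, omega))
        return flat.reshape(x.shape[0], self.state_dim, self.noise_dim)

    @property
    def params(self):
        p = list(self.drift_net.params)
        if self.diffusion_net is not None:
            p += self.diffusion_net.params
        return p


_OVERFLOW = 1e6


def em_integrate(field: SDEField, x0, omega, times, n_traj: int, seed: int,
                 metadata: Optional[Dict] = None) -> TrajectoryEnsemble:
    """Euler--Maruyama simulation of an SDE field on a fixed grid.

    ``x0`` is either a single state (shared by all trajectories) or one row
    per trajectory.  Wiener increments are Normal(0, dt_j I) and independent
    across trajectories and steps; the run is deterministic for a fixed seed.
    """
    times = np.asarray(times, dtype=float).ravel()
    if times.size < 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("times must be non-empty and strictly increasing")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim == 1:
        x0 = np.broadcast_to(x0, (n_traj, x0.size)).copy()
    elif x0.shape[0] != n_traj:
        raise ValueError(f"x0 has {x0.shape[0]} rows but n_traj={n_traj}")
    d = x0.shape[1]
    if d != field.state_dim:
        raise ValueError(f"x0 dimension {d} != field state_dim {field.state_dim}")
    rng = np.random.default_rng(seed)
    T = times.size
    out = np.empty((n_traj, T, d))
    out[:, 0] = x0
    x = x0.copy()
    for j in range(T - 1):
        dt = times[j + 1] - times[j]
        f = field.drift(x, omega)
        g = field.diffusion(x, omega)
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite drift/diffusion at step {j}")
        db = rng.normal(0.0, np.sqrt(dt), size=(n_traj, field.noise_dim))
        x = x + f * dt + np.einsum("ndm,nm->nd", g, db)
        if np.any(np.abs(x) > _OVERFLOW):
            raise FloatingPointError(
                f"state overflow (|x| > {_OVERFLOW:g}) at step {j + 1}")
        out[:, j + 1] = x
    meta = {"seed": int(seed)}
    if metadata:
        meta.update(metadata)
    return TrajectoryEnsemble(times=times, values=out, omega=np.atleast_1d(omega),
                              metadata=meta)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grad(pred: np.ndarray, obs: np.ndarray, weights: np.ndarray,
                   mask: Optional[np.ndarray]) -> Tuple[float, np.ndarray]:
    """Temporally decoupled squared W2 of one omega stratum and its gradient.

    ``pred``/``obs`` have shape (n, T, d); returns (loss, dloss/dpred).
    Uses the order-statistics coupling per (time, component); ties are
    broken by stable argsort so the subgradient is deterministic.
    """
    n = pred.shape[0]
    order = np.argsort(pred, axis=0, kind="stable")
    pred_sorted = np.take_along_axis(pred, order, axis=0)
    obs_sorted = np.sort(obs, axis=0)
    diff = pred_sorted - obs_sorted                       # (n, T, d)
    w = weights[None, :, None]
    if mask is not None:
        w = w * mask[None, None, :]
    loss = float(np.sum(w[0] * np.mean(diff**2, axis=0)))
    grad_sorted = 2.0 * diff / n * w
    grad = np.empty_like(pred)
    np.put_along_axis(grad, order, grad_sorted, axis=0)
    return loss, grad


@dataclass
class _Batch:
    times: np.ndarray
    x0: np.ndarray            # (N, d)
    omega_rows: np.ndarray    # (N, p)
    obs: np.ndarray           # (N, T, d) observed values, rows grouped by entry
    slices: List[Tuple[Tuple[float, ...], slice]]


class EndNSDE:
    """Extrinsic-noise-driven neural SDE model over a parameter grid.

    Parameters
    ----------
    grid:
        Training data; only entries tagged ``train`` are used for fitting.
    config:
        :class:`~endnsde.data.RunConfig` with network and optimizer settings.
    """

    def __init__(self, grid: ExtrinsicParamGrid, config: RunConfig) -> None:
        train = [e for e in grid.entries if e.split == "train"]
        if not train:
            raise ValueError("grid contains no training ensembles")
        self.grid = grid
        self.config = config
        d = train[0].ensemble.state_dim
        p = train[0].ensemble.omega.size
        for e in train:
            if e.ensemble.state_dim != d or e.ensemble.omega.size != p:
                raise ValueError("inconsistent state/parameter dimensions across grid")
        self.state_dim = d
        self.param_dim = p
        self.noise_dim = config.noise_dim or d
        self._batches = self._build_batches(train, max(1, int(config.n_pred_factor)))

    @staticmethod
    def _build_batches(entries: List[GridEntry], k: int = 1) -> List[_Batch]:
        """Stack entries sharing a time grid into training batches.

        With ``k`` > 1 every observed trajectory seeds ``k`` predicted ones
        and observed samples are duplicated ``k``-fold; duplication leaves
        the empirical measure (hence the W2 loss scale) unchanged while the
        extra simulated paths reduce gradient noise.
        """
        groups: Dict[Tuple, List[GridEntry]] = {}
        for e in entries:
            key = tuple(np.round(e.ensemble.times, 12))
            groups.setdefault(key, []).append(e)
        batches = []
        for key, group in groups.items():
            times = group[0].ensemble.times
            x0 = np.concatenate([
                np.repeat(e.ensemble.initial_states(), k, axis=0) for e in group])
            omega_rows = np.concatenate([
                np.broadcast_to(e.omega, (k * e.ensemble.n_traj, e.omega.size))
                for e in group])
            obs = np.concatenate([
                np.repeat(e.ensemble.values, k, axis=0) for e in group])
            slices, start = [], 0
            for e in group:
                n = k * e.ensemble.n_traj
                slices.append((e.omega_key, slice(start, start + n)))
                start += n
            batches.append(_Batch(times=times, x0=x0, omega_rows=omega_rows,
                                  obs=obs, slices=slices))
        return batches

    # -- one training epoch on one batch ---------------------------------
    def _epoch(self, batch: _Batch, field: NeuralSDEField, grads: List[np.ndarray],
               rng: np.random.Generator, mask: Optional[np.ndarray]) -> float:
        cfg = self.config
        times = batch.times
        T = times.size
        N, d = batch.x0.shape
        m = self.noise_dim
        dts = np.diff(times)
        X = np.empty((N, T, d))
        X[:, 0] = batch.x0
        caches = []
        zero_diff = field.zero_diffusion
        for j in range(T - 1):
            inp = np.concatenate([X[:, j], batch.omega_rows], axis=1)
            f, f_cache = field.drift_net.forward(inp)
            if zero_diff:
                g_flat, g_cache, db = None, None, None
                X[:, j + 1] = X[:, j] + f * dts[j]
            else:
                g_flat, g_cache = field.diffusion_net.forward(inp)
                g = g_flat.reshape(N, d, m)
                db = rng.normal(0.0, np.sqrt(dts[j]), size=(N, m))
                X[:, j + 1] = X[:, j] + f * dts[j] + np.einsum("ndm,nm->nd", g, db)
            if np.any(np.abs(X[:, j + 1]) > _OVERFLOW):
                raise FloatingPointError(f"training simulation overflow at step {j + 1}")
            caches.append((f_cache, g_cache, db))

        # loss and its gradient with respect to every simulated state
        weights = quadrature_weights(times)
        total = 0.0
        G = np.zeros_like(X)
        for omega_key, sl in batch.slices:
            loss, grad = _loss_and_grad(X[sl], batch.obs[sl], weights, mask)
            total += loss
            G[sl] = grad

        # reverse pass through the Euler--Maruyama unroll
        n_drift = len(field.drift_net.params)
        drift_grads = grads[:n_drift]
        diff_grads = grads[n_drift:]
        A = G[:, T - 1].copy()
        for j in range(T - 2, -1, -1):
            f_cache, g_cache, db = caches[j]
            dinp = field.drift_net.backward(f_cache, A * dts[j], drift_grads)
            dX = A + dinp[:, :d]
            if not zero_diff:
                dg = (A[:, :, None] * db[:, None, :]).reshape(N, d * m)
                dinp_g = field.diffusion_net.backward(g_cache, dg, diff_grads)
                dX += dinp_g[:, :d]
            A = dX + G[:, j]
        return total

    def fit(self, verbose: bool = False, callback=None) -> "EndNSDEResults":
        cfg = self.config
        rng_init = np.random.default_rng(substream(cfg.seed, "init"))
        field = NeuralSDEField(
            self.state_dim, self.param_dim, self.noise_dim, cfg.hidden, rng_init,
            drift_out_scale=cfg.drift_out_scale,
            diffusion_out_scale=cfg.diffusion_out_scale,
            latent_mask=cfg.latent_mask, zero_diffusion=cfg.zero_diffusion)
        mask = None
        if cfg.latent_mask is not None:
            mask = np.zeros(self.state_dim)
            mask[list(cfg.latent_mask)] = 1.0
        opt = Adam(field.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        history: List[float] = []
        # per-parameter averaging decay: drift and diffusion nets converge on
        # different time scales, so they get separate windows (0 = no average)
        n_drift = len(field.drift_net.params)
        decays = [cfg.ema_decay] * n_drift
        decays += [cfg.ema_decay_diffusion] * (len(field.params) - n_drift)
        use_ema = any(d > 0 for d in decays)
        ema = [p.copy() for p in field.params] if use_ema else None
        t0 = _time.perf_counter()
        for epoch in range(cfg.imax):
            if cfg.lr_schedule == "cosine":
                frac = epoch / max(cfg.imax - 1, 1)
                opt.lr = cfg.lr * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))
            rng = np.random.default_rng(substream(cfg.seed, f"train-noise:{epoch}"))
            grads = [np.zeros_like(p) for p in field.params]
            total = 0.0
            for batch in self._batches:
                total += self._epoch(batch, field, grads, rng, mask)
            if not np.isfinite(total):
                raise FloatingPointError(f"divergent loss at epoch {epoch}")
            global_norm_clip(grads, cfg.grad_clip)
            opt.step(grads)
            if ema is not None:
                for e, p, d in zip(ema, field.params, decays):
                    if d > 0:
                        e *= d
                        e += (1 - d) * p
                    else:
                        e[...] = p
            history.append(total)
            if callback is not None:
                callback(epoch, total)
            if verbose and (epoch % 25 == 0 or epoch == cfg.imax - 1):
                print(f"epoch {epoch:4d}  loss {total:.6f}  "
                      f"[{_time.perf_counter() - t0:.1f}s]")
        if ema is not None:
            for p, e, d in zip(field.params, ema, decays):
                if d > 0:
                    p[...] = e
        return EndNSDEResults(model=self, field=field, loss_history=history)


@dataclass
class EndNSDEResults:
    """Fitted END-nSDE: learned field, loss history, prediction and summary."""

    model: EndNSDE
    field: NeuralSDEField
    loss_history: List[float]

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def predict(self, x0, omega, times, n_traj: int, seed: int) -> TrajectoryEnsemble:
        """Simulate the learned SDE; omega may lie outside the training grid."""
        seen = tuple(float(v) for v in np.atleast_1d(omega)) in set(
            self.model.grid.omegas())
        return em_integrate(self.field, x0, omega, times, n_traj, seed,
                            metadata={"omega_seen_in_training": bool(seen)})

    def predict_grid(self, grid: ExtrinsicParamGrid, seed: int,
                     split: Optional[str] = None) -> ExtrinsicParamGrid:
        """Simulate a matched ensemble for every entry of ``grid``."""
        entries = []
        for i, e in enumerate(grid.entries):
            if split is not None and e.split != split:
                continue
            ens = e.ensemble
            pred = self.predict(ens.initial_states(), e.omega, ens.times,
                                ens.n_traj, substream(seed, f"predict:{i}"))
            entries.append(GridEntry(e.omega, pred, e.split))
        return ExtrinsicParamGrid(entries=entries, metadata={"predicted": True})

    def evaluate(self, grid: ExtrinsicParamGrid, seed: int = 0,
                 split: Optional[str] = None) -> LossReport:
        """Extrinsic-noise-driven W2 loss of fresh predictions against ``grid``."""
        from .wasserstein import extrinsic_loss
        ref = grid if split is None else grid.select(split)
        pred = self.predict_grid(ref, seed)
        comps = list(self.field.latent_mask) if self.field.latent_mask else None
        return extrinsic_loss(ref, pred, components=comps)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Extrinsic-noise-driven neural SDE — fit summary",
            "=" * 48,
            f"state dim:        {self.model.state_dim}",
            f"param dim:        {self.model.param_dim}",
            f"noise dim:        {self.model.noise_dim}",
            f"hidden layers:    {cfg.hidden}",
            f"epochs run:       {len(self.loss_history)} (imax {cfg.imax})",
            f"learning rate:    {cfg.lr:g}",
            f"seed:             {cfg.seed}",
            f"initial W2 loss:  {self.loss_history[0]:.6f}",
            f"final W2 loss:    {self.loss_history[-1]:.6f}",
            f"training strata:  {len(self.model.grid.select('train').entries)} omega values",
        ]
        if cfg.latent_mask is not None:
            lines.append(f"loss components:  {list(cfg.latent_mask)} (others latent)")
        return "\n".join(lines)

    # ---- plotting (matplotlib is an optional extra) ---------------------
    def plot_loss(self, ax=None):
        """Training-loss trace over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("extrinsic-noise W2 loss")
        ax.set_yscale("log")
        return ax

    def plot_fit(self, ensemble: TrajectoryEnsemble, component: int = 0,
                 n_traj: int = 20, seed: int = 0, ax=None):
        """Observed vs simulated trajectories for one stratum and component."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict(ensemble.initial_states(), ensemble.omega,
                            ensemble.times, ensemble.n_traj, seed)
        for v in ensemble.values[:n_traj, :, component]:
            ax.plot(ensemble.times, v, color="C0", alpha=0.3, lw=0.8)
        for v in pred.values[:n_traj, :, component]:
            ax.plot(pred.times, v, color="C3", alpha=0.3, lw=0.8, ls="--")
        ax.set_xlabel("time")
        label = (ensemble.state_labels[component]
                 if ensemble.state_labels else f"x_{component + 1}")
        ax.set_ylabel(label)
        ax.set_title(f"omega = {tuple(np.round(ensemble.omega, 4))}")
        return ax

    # ---- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Write weights + config + loss history to an HDF5 checkpoint."""
        import json

        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["config"] = json.dumps(self.config.to_dict())
            fh.attrs["dims"] = json.dumps({
                "state_dim": self.model.state_dim,
                "param_dim": self.model.param_dim,
                "noise_dim": self.model.noise_dim,
                "zero_diffusion": self.field.zero_diffusion,
            })
            fh.create_dataset("loss_history", data=np.asarray(self.loss_history))
            g = fh.create_group("drift")
            for i, p in enumerate(self.field.drift_net.params):
                g.create_dataset(f"p{i}", data=p)
            if self.field.diffusion_net is not None:
                g = fh.create_group("diffusion")
                for i, p in enumerate(self.field.diffusion_net.params):
                    g.create_dataset(f"p{i}", data=p)


def load_results(path, grid: Optional[ExtrinsicParamGrid] = None) -> EndNSDEResults:
    """Restore a fitted model from :meth:`EndNSDEResults.save`.

    ``grid`` is only needed if further prediction bookkeeping (seen-omega
    tagging) should refer to the original training grid; a minimal stub is
    used otherwise.
    """
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        cfg = RunConfig.from_dict(json.loads(fh.attrs["config"]))
        dims = json.loads(fh.attrs["dims"])
        history = [float(v) for v in fh["loss_history"][()]]
        drift_params = [fh["drift"][f"p{i}"][()] for i in range(len(fh["drift"]))]
        diff_params = None
        if "diffusion" in fh:
            diff_params = [fh["diffusion"][f"p{i}"][()] for i in range(len(fh["diffusion"]))]
    rng = np.random.default_rng(0)
    field = NeuralSDEField(
        dims["state_dim"], dims["param_dim"], dims["noise_dim"], cfg.hidden, rng,
        latent_mask=cfg.latent_mask, zero_diffusion=dims["zero_diffusion"])
    nw = len(field.drift_net.weights)
    field.drift_net.weights = drift_params[:nw]
    field.drift_net.biases = drift_params[nw:]
    if diff_params is not None:
        field.diffusion_net.weights = diff_params[:nw]
        field.diffusion_net.biases = diff_params[nw:]
    if grid is None:
        # stub grid: a single empty reference so predict() bookkeeping works
        dummy = TrajectoryEnsemble(
            times=np.array([0.0, 1.0]),
            values=np.zeros((1, 2, dims["state_dim"])),
            omega=np.zeros(dims["param_dim"]))
        grid = ExtrinsicParamGrid(entries=[GridEntry(dummy.omega, dummy, "train")])
    model = EndNSDE(grid, cfg)
    return EndNSDEResults(model=model, field=field, loss_history=history)
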