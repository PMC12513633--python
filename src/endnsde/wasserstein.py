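"""Empirical Wasserstein-2 machinery for trajectory-ensemble losses.

The training objective used throughout the package is the *temporally
decoupled* squared W2 distance: at every observation time the empirical
marginal of the predicted ensemble is compared with the observed marginal,
one state component at a time, and the per-time squared W2 values are
integrated over the horizon with a left-Riemann rule.  Summing that
quantity over the finite set of extrinsic-parameter values (the strata of
the heterogeneous population) gives the extrinsic-noise-driven loss.

For one-dimensional empirical measures with equal sample counts the
squared W2 distance has a closed form: sort both samples and average the
squared differences of order statistics.  That form is exact, cheap, and
differentiable almost everywhere with respect to the samples, which is
what makes it usable as a training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "LossReport",
    "marginal_w2_squared",
    "marginal_w2_squared_grad",
    "temporal_w2_squared",
    "extrinsic_loss",
    "equalize_counts",
]


@dataclass
class LossReport:
    """Decomposition of the extrinsic-noise-driven loss over parameter strata.

    ``total`` always equals the sum of the ``per_omega`` entries;
    ``per_time`` (optional) holds the per-(omega, time) integrand terms,
    i.e. quadrature-weighted per-time squared W2 values.
    """

    total: float
    per_omega: Dict[Tuple[float, ...], float]
    per_time: Optional[Dict[Tuple[float, ...], np.ndarray]] = field(default=None)

    def __post_init__(self) -> None:
        s = float(sum(self.per_omega.values()))
        if not np.isclose(self.total, s, rtol=1e-9, atol=1e-12):
            raise ValueError(f"total {self.total} != sum of per_omega {s}")
        if any(v < -1e-12 for v in self.per_omega.values()):
            raise ValueError("negative per-omega loss entry")


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample set")
    return a


def marginal_w2_squared(samples_a, samples_b) -> float:
    """Exact squared W2 between two 1-D empirical measures of equal size.

    Equals the mean squared difference of order statistics (the optimal
    coupling of two 1-D empirical measures pairs sorted samples).
    """
    a = _as_1d(samples_a)
    b = _as_1d(samples_b)
    if a.size != b.size:
        raise ValueError(f"sample counts differ: {a.size} vs {b.size}")
    return float(np.mean((np.sort(a) - np.sort(b)) ** 2))


def marginal_w2_squared_grad(samples_a, samples_b) -> np.ndarray:
    """Gradient of ``marginal_w2_squared`` with respect to ``samples_b``.

    Away from ties the order-statistics coupling is locally constant, so
    d/db_k = 2 (b_k - a_matched(k)) / n with a_matched the observed sample
    paired with b_k in the sorted coupling.  Ties are broken by stable
    argsort on the sample index, which makes the subgradient deterministic.
    """
    a = _as_1d(samples_a)
    b = _as_1d(samples_b)
    if a.size != b.size:
        raise ValueError(f"sample counts differ: {a.size} vs {b.size}")
    order_b = np.argsort(b, kind="stable")
    a_sorted = np.sort(a)
    grad = np.empty_like(b)
    grad[order_b] = 2.0 * (b[order_b] - a_sorted) / b.size
    return grad


def _check_pair(observed, predicted) -> None:
    if observed.values.shape[2] != predicted.values.shape[2]:
        raise ValueError(
            f"state dimension mismatch: {observed.values.shape[2]} vs "
            f"{predicted.values.shape[2]}"
        )
    if observed.times.shape != predicted.times.shape or not np.allclose(
        observed.times, predicted.times
    ):
        raise ValueError("time grids differ between observed and predicted ensembles")
    if observed.n_traj != predicted.n_traj:
        raise ValueError(
            f"trajectory counts differ ({observed.n_traj} vs {predicted.n_traj}); "
            "equalize with equalize_counts() first"
        )


def per_time_w2_matrix(observed_values: np.ndarray, predicted_values: np.ndarray) -> np.ndarray:
    """Squared W2 per (time, component): shape (T, d), vectorized over the grid."""
    diff = np.sort(observed_values, axis=0) - np.sort(predicted_values, axis=0)
    return np.mean(diff**2, axis=0)


def quadrature_weights(times: np.ndarray) -> np.ndarray:
    """Left-Riemann weights on the grid: dt_j at t_j for j < T-1, 0 at t_{T-1}."""
    w = np.zeros_like(times, dtype=float)
    w[:-1] = np.diff(times)
    return w


def temporal_w2_squared(observed, predicted, components=None, return_per_time: bool = False):
    """Temporally decoupled squared W2 between two ensembles on a common grid.

    Per-time marginals are compared one state component at a time (sum over
    components), and the per-time values are integrated with a left-Riemann
    rule, so non-uniform grids are handled through their dt_j weights.

    ``components`` restricts the loss to a subset of state components
    (the latent-variable mask of partially observed systems).
    """
    _check_pair(observed, predicted)
    obs = observed.values
    pred = predicted.values
    if components is not None:
        idx = np.asarray(components, dtype=int)
        obs = obs[:, :, idx]
        pred = pred[:, :, idx]
    per_td = per_time_w2_matrix(obs, pred)  # (T, d)
    w = quadrature_weights(observed.times)
    per_time = w * per_td.sum(axis=1)
    total = float(per_time.sum())
    if return_per_time:
        return total, per_time
    return total


def equalize_counts(ensemble, n: int, seed: int):
    """Seeded subsample of an ensemble down to ``n`` trajectories."""
    if n > ensemble.n_traj:
        raise ValueError(f"cannot subsample {ensemble.n_traj} trajectories to {n}")
    if n == ensemble.n_traj:
        return ensemble
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(ensemble.n_traj, size=n, replace=False))
    return ensemble.subset(keep)


def extrinsic_loss(grid_observed, grid_predicted, components=None,
                   return_per_time: bool = False, equalize_seed: int = 0) -> LossReport:
    """Sum of temporally decoupled squared W2 over the extrinsic-parameter set.

    Both grids must cover the same omega values; paired ensembles with
    unequal trajectory counts are equalized by seeded subsampling of the
    larger one.
    """
    obs_map = {e.omega_key: e.ensemble for e in grid_observed.entries}
    pred_map = {e.omega_key: e.ensemble for e in grid_predicted.entries}
    if set(obs_map) != set(pred_map):
        only_obs = set(obs_map) - set(pred_map)
        only_pred = set(pred_map) - set(obs_map)
        raise ValueError(
            f"omega sets differ: only observed {sorted(only_obs)}, "
            f"only predicted {sorted(only_pred)}"
        )
    per_omega: Dict[Tuple[float, ...], float] = {}
    per_time: Dict[Tuple[float, ...], np.ndarray] = {}
    for key in obs_map:
        o, p = obs_map[key], pred_map[key]
        n = min(o.n_traj, p.n_traj)
        o = equalize_counts(o, n, equalize_seed)
        p = equalize_counts(p, n, equalize_seed + 1)
        val, pt = temporal_w2_squared(o, p, components=components, return_per_time=True)
        per_omega[key] = val
        per_time[key] = pt
    total = float(sum(per_omega.values()))
    return LossReport(
        total=total,
        per_omega=per_omega,
        per_time=per_time if return_per_time else None,
    )
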