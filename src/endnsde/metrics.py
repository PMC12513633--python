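"""Evaluation metrics for reconstructed SDE fields.

Relative drift error: for each trajectory, the l1 deviation between the
true and learned drift summed along the trajectory, divided by the summed
l1 magnitude of the true drift, then averaged over trajectories.  The
diffusion analogue compares sigma sigma^T entrywise-absolutely, which makes
it invariant to the right-orthogonal gauge freedom of the diffusion
factor.  Both metrics evaluate the learned field at the *observed* states
(teacher-forced), which is the only construction that pairs trajectory
indices coherently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .data import ExtrinsicParamGrid, TrajectoryEnsemble
from .model import SDEField

__all__ = ["ErrorReport", "drift_error", "diffusion_error",
           "cosine_similarity", "heatmap_table", "evaluate_fields"]


@dataclass
class ErrorReport:
    """Per-omega drift/diffusion/W2 metrics with their arithmetic means."""

    drift: Dict[Tuple[float, ...], float] = field(default_factory=dict)
    diffusion: Dict[Tuple[float, ...], float] = field(default_factory=dict)
    w2: Dict[Tuple[float, ...], float] = field(default_factory=dict)

    @staticmethod
    def _mean(d: Dict) -> float:
        return float(np.mean(list(d.values()))) if d else float("nan")

    @property
    def mean_drift(self) -> float:
        return self._mean(self.drift)

    @property
    def mean_diffusion(self) -> float:
        return self._mean(self.diffusion)

    @property
    def mean_w2(self) -> float:
        return self._mean(self.w2)


def _field_values(fieldobj: SDEField, ensemble: TrajectoryEnsemble, which: str) -> np.ndarray:
    """Evaluate a field along every observed state; (n, T, d) or (n, T, d, m)."""
    n, T, d = ensemble.values.shape
    flat = ensemble.values.reshape(n * T, d)
    if which == "drift":
        out = fieldobj.drift(flat, ensemble.omega)
        return np.asarray(out).reshape(n, T, -1)
    out = fieldobj.diffusion(flat, ensemble.omega)
    out = np.asarray(out)
    return out.reshape(n, T, out.shape[1], out.shape[2])


def drift_error(true_field: SDEField, learned_field: SDEField,
                ensemble: TrajectoryEnsemble) -> float:
    """Mean over trajectories of sum_j |f - f_hat|_1 / sum_j |f|_1 along each
    trajectory, both fields evaluated at the observed states."""
    f = _field_values(true_field, ensemble, "drift")
    fh = _field_values(learned_field, ensemble, "drift")
    num = np.abs(f - fh).sum(axis=(1, 2))          # per trajectory
    den = np.abs(f).sum(axis=(1, 2))
    ok = den > 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} trajectories with all-zero true "
                      "drift excluded from the drift error")
    if not np.any(ok):
        raise ValueError("drift error undefined: true drift vanishes everywhere")
    return float(np.mean(num[ok] / den[ok]))


def diffusion_error(true_field: SDEField, learned_field: SDEField,
                    ensemble: TrajectoryEnsemble) -> float:
    """Relative error of sigma sigma^T in the entrywise-absolute matrix norm.

    Comparing through |sigma sigma^T| makes the metric blind to the sign
    and to any right-orthogonal refactoring of either diffusion matrix.
    """
    s = _field_values(true_field, ensemble, "diffusion")
    sh = _field_values(learned_field, ensemble, "diffusion")
    ssT = np.einsum("ntij,ntkj->ntik", s, s)
    shshT = np.einsum("ntij,ntkj->ntik", sh, sh)
    num = np.abs(np.abs(ssT) - np.abs(shshT)).sum(axis=(1, 2, 3))
    den = np.abs(ssT).sum(axis=(1, 2, 3))
    ok = den > 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} trajectories with identically zero "
                      "true diffusion excluded from the diffusion error")
    if not np.any(ok):
        raise ValueError("diffusion error undefined: true diffusion vanishes everywhere")
    return float(np.mean(num[ok] / den[ok]))


def cosine_similarity(traj_a, traj_b) -> float:
    """Inner product over the product of norms for two sampled trajectories."""
    a = np.asarray(traj_a, dtype=float).ravel()
    b = np.asarray(traj_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("trajectories must share the sampling grid")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm trajectory")
    return float(np.dot(a, b) / (na * nb))


def evaluate_fields(true_field: SDEField, learned_field: SDEField,
                    grid: ExtrinsicParamGrid,
                    w2_per_omega: Optional[Dict] = None) -> ErrorReport:
    """Drift and diffusion errors per omega over a grid (optionally merging
    per-omega W2 values computed elsewhere)."""
    report = ErrorReport()
    for e in grid.entries:
        report.drift[e.omega_key] = drift_error(true_field, learned_field, e.ensemble)
        report.diffusion[e.omega_key] = diffusion_error(true_field, learned_field,
                                                        e.ensemble)
    if w2_per_omega:
        report.w2.update(w2_per_omega)
    return report


def heatmap_table(per_omega: Dict[Tuple[float, ...], Dict[str, float]],
                  split_tags: Optional[Dict[Tuple[float, ...], str]] = None,
                  param_labels: Optional[Tuple[str, ...]] = None) -> pd.DataFrame:
    """Long-format table (omega components, metric, value, split) for plotting.

    ``per_omega`` maps omega -> {metric name: value}; heldout omegas are
    flagged through ``split_tags``.
    """
    rows = []
    for omega, metrics in per_omega.items():
        omega = tuple(np.atleast_1d(omega))
        labels = param_labels or tuple(f"omega_{i + 1}" for i in range(len(omega)))
        base = dict(zip(labels, omega))
        base["split"] = (split_tags or {}).get(tuple(omega), "train")
        for metric, value in metrics.items():
            rows.append({**base, "metric": metric, "value": value})
    columns = None
    if rows:
        columns = list(rows[0].keys())
    return pd.DataFrame(rows, columns=columns)
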