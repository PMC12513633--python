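"""Core containers and on-disk formats for trajectory ensembles.

An ensemble is a set of trajectories observed on a common time grid, all
sharing the same extrinsic-parameter vector omega (the stratum of the
heterogeneous population they were measured in).  A grid collects the
ensembles for a finite set of omega values together with their
train/test/heldout membership.

Two interchangeable on-disk layouts are provided: a human-inspectable
columnar text dialect (header ``traj_id,t,x_1..x_d`` with omega and labels
in a ``#``-prefixed JSON header line) and an HDF5 container with one group
per omega for bulk storage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "GridEntry",
    "ExtrinsicParamGrid",
    "RunConfig",
    "write_ensemble",
    "read_ensemble",
    "write_grid",
    "read_grid",
    "split_grid",
    "substream",
]

SPLITS = ("train", "test", "heldout")


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from one master seed.

    All randomness in the package flows from a single seed through named
    substreams (simulation, splitting, initialization, training, ...) so
    that runs are reproducible end to end.
    """
    h = zlib.crc32(name.encode("utf8"))
    return int((int(seed) * 2654435761 + h) % (2**31 - 1))


def _omega_key(omega: np.ndarray) -> Tuple[float, ...]:
    return tuple(float(v) for v in np.atleast_1d(omega))


@dataclass
class TrajectoryEnsemble:
    """Trajectories on a common strictly increasing time grid.

    ``values`` is indexed (trajectory, time index, state component); every
    trajectory in the ensemble shares the identical ``omega`` vector.
    """

    times: np.ndarray
    values: np.ndarray
    omega: np.ndarray
    state_labels: Optional[List[str]] = None
    param_labels: Optional[List[str]] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float)
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (n_traj, n_times, state_dim); got shape {self.values.shape}"
            )
        n, t, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one trajectory and one state component")
        if t != self.times.size:
            raise ValueError(f"{t} value columns vs {self.times.size} grid times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j, k = bad[0]
            raise ValueError(
                f"non-finite value at trajectory {i}, time index {j}, component {k}"
            )
        if self.state_labels is not None and len(self.state_labels) != d:
            raise ValueError("state_labels length mismatch")
        if self.param_labels is not None and len(self.param_labels) != self.omega.size:
            raise ValueError("param_labels length mismatch")

    # ---- conveniences ----------------------------------------------------
    @property
    def n_traj(self) -> int:
        return self.values.shape[0]

    @property
    def state_dim(self) -> int:
        return self.values.shape[2]

    @property
    def omega_key(self) -> Tuple[float, ...]:
        return _omega_key(self.omega)

    def subset(self, indices: Sequence[int]) -> "TrajectoryEnsemble":
        return replace(self, values=self.values[np.asarray(indices, dtype=int)])

    def initial_states(self) -> np.ndarray:
        """First-grid-time states, shape (n_traj, state_dim)."""
        return self.values[:, 0, :].copy()

    def component(self, index: int) -> np.ndarray:
        return self.values[:, :, index]

    def allclose(self, other: "TrajectoryEnsemble", rtol=1e-9, atol=1e-12) -> bool:
        return (
            np.allclose(self.times, other.times, rtol=rtol, atol=atol)
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
            and np.allclose(self.omega, other.omega, rtol=rtol, atol=atol)
        )


@dataclass
class GridEntry:
    omega: np.ndarray
    ensemble: TrajectoryEnsemble
    split: str = "train"

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if not np.allclose(self.omega, self.ensemble.omega):
            raise ValueError("entry omega differs from its ensemble's omega")

    @property
    def omega_key(self) -> Tuple[float, ...]:
        return _omega_key(self.omega)


@dataclass
class ExtrinsicParamGrid:
    """The finite set of extrinsic-parameter values with their ensembles.

    Omega vectors are unique per split tag (one omega may legitimately
    carry both a train and a test ensemble after a within-omega split).
    """

    entries: List[GridEntry]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.omega_key, e.split)
            if key in seen:
                raise ValueError(f"duplicate omega {e.omega_key} within split {e.split!r}")
            seen.add(key)

    def omegas(self) -> List[Tuple[float, ...]]:
        out: List[Tuple[float, ...]] = []
        for e in self.entries:
            if e.omega_key not in out:
                out.append(e.omega_key)
        return out

    def select(self, split: str) -> "ExtrinsicParamGrid":
        return ExtrinsicParamGrid(
            entries=[e for e in self.entries if e.split == split],
            metadata=dict(self.metadata),
        )

    @property
    def n_traj_total(self) -> int:
        return sum(e.ensemble.n_traj for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RunConfig:
    """Hyperparameters of a training / simulation run.

    ``imax`` is the maximum number of training epochs; ``hidden`` are the
    hidden-layer widths of the drift and diffusion networks; the seed is
    the single source of randomness and is recorded in every artifact.
    """

    seed: int = 0
    dt: float = 0.02
    horizon: float = 1.0
    imax: int = 300
    hidden: Tuple[int, ...] = (48, 48)
    lr: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to lr/50 at imax)
    noise_dim: Optional[int] = None
    drift_out_scale: float = 0.1
    diffusion_out_scale: float = 0.05
    grad_clip: float = 50.0
    weight_decay: float = 0.0
    ema_decay: float = 0.0  # >0 averages drift-net weights (e.g. 0.998)
    ema_decay_diffusion: float = 0.0  # separate window for the diffusion net
    n_pred_factor: int = 1  # predicted trajectories per observed one
    latent_mask: Optional[Tuple[int, ...]] = None
    zero_diffusion: bool = False
    extra: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")
        if self.imax < 1:
            raise ValueError("imax must be >= 1")

    def to_dict(self) -> Dict:
        d = {
            "seed": self.seed, "dt": self.dt, "horizon": self.horizon,
            "imax": self.imax, "hidden": list(self.hidden), "lr": self.lr,
            "lr_schedule": self.lr_schedule,
            "noise_dim": self.noise_dim, "drift_out_scale": self.drift_out_scale,
            "diffusion_out_scale": self.diffusion_out_scale,
            "grad_clip": self.grad_clip,
            "weight_decay": self.weight_decay,
            "ema_decay": self.ema_decay,
            "ema_decay_diffusion": self.ema_decay_diffusion,
            "n_pred_factor": self.n_pred_factor,
            "latent_mask": list(self.latent_mask) if self.latent_mask else None,
            "zero_diffusion": self.zero_diffusion,
        }
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {k: d[k] for k in (
            "seed", "dt", "horizon", "imax", "lr", "lr_schedule", "noise_dim",
            "drift_out_scale", "diffusion_out_scale", "grad_clip",
            "weight_decay", "ema_decay", "ema_decay_diffusion", "n_pred_factor",
            "zero_diffusion") if k in d}
        if "hidden" in d:
            known["hidden"] = tuple(d["hidden"])
        if d.get("latent_mask"):
            known["latent_mask"] = tuple(d["latent_mask"])
        extra = {k: v for k, v in d.items() if k not in known and k != "latent_mask"}
        return cls(**known, extra=extra)


# ---------------------------------------------------------------------------
# columnar-text / HDF5 round trip
# ---------------------------------------------------------------------------

def _text_header(ensemble: TrajectoryEnsemble) -> str:
    meta = {
        "omega": [float(v) for v in ensemble.omega],
        "state_labels": ensemble.state_labels,
        "param_labels": ensemble.param_labels,
        "metadata": _jsonable(ensemble.metadata),
    }
    return "# " + json.dumps(meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_ensemble(ensemble: TrajectoryEnsemble, path, format: str = "columnar-text"):
    """Write one ensemble; round-trip through :func:`read_ensemble` is the identity."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    bad = np.argwhere(~np.isfinite(ensemble.values))
    if bad.size:
        i, j, k = bad[0]
        raise ValueError(
            f"non-finite value at trajectory {i}, time index {j}, component {k}")
    if format == "columnar-text":
        n, t, d = ensemble.values.shape
        traj_id = np.repeat(np.arange(n), t)
        times = np.tile(ensemble.times, n)
        flat = ensemble.values.reshape(n * t, d)
        df = pd.DataFrame({"traj_id": traj_id, "t": times})
        for k in range(d):
            df[f"x_{k + 1}"] = flat[:, k]
        with open(path, "w") as fh:
            fh.write(_text_header(ensemble) + "\n")
            df.to_csv(fh, index=False, lineterminator="\n")
    elif format == "hierarchical-binary":
        with h5py.File(path, "w") as fh:
            _write_ensemble_h5(fh, ensemble)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _write_ensemble_h5(group, ensemble: TrajectoryEnsemble) -> None:
    group.create_dataset("times", data=ensemble.times)
    group.create_dataset("values", data=ensemble.values)
    group.create_dataset("omega", data=ensemble.omega)
    group.attrs["meta"] = json.dumps({
        "state_labels": ensemble.state_labels,
        "param_labels": ensemble.param_labels,
        "metadata": _jsonable(ensemble.metadata),
    })


def _read_ensemble_h5(group) -> TrajectoryEnsemble:
    meta = json.loads(group.attrs.get("meta", "{}"))
    return TrajectoryEnsemble(
        times=group["times"][()],
        values=group["values"][()],
        omega=group["omega"][()],
        state_labels=meta.get("state_labels"),
        param_labels=meta.get("param_labels"),
        metadata=meta.get("metadata") or {},
    )


def read_ensemble(path) -> TrajectoryEnsemble:
    """Read an ensemble written by :func:`write_ensemble` (either format)."""
    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            return _read_ensemble_h5(fh)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first[1:]) if first.startswith("#") else {}
        df = pd.read_csv(fh) if first.startswith("#") else pd.read_csv(path)
    if "t" not in df.columns or "traj_id" not in df.columns:
        raise ValueError("missing 'traj_id'/'t' columns in columnar trajectory file")
    state_cols = [c for c in df.columns if c.startswith("x_")]
    df = df.sort_values(["traj_id", "t"], kind="stable")
    times = np.unique(df["t"].to_numpy())
    n = df["traj_id"].nunique()
    if len(df) != n * times.size:
        raise ValueError("ragged time grids across trajectories")
    for tid, sub in df.groupby("traj_id"):
        if not np.array_equal(sub["t"].to_numpy(), times):
            raise ValueError(f"trajectory {tid} not on the common time grid")
    values = df[state_cols].to_numpy().reshape(n, times.size, len(state_cols))
    omega = np.asarray(meta.get("omega", []), dtype=float)
    if omega.size == 0:
        omega = np.zeros(1)
    return TrajectoryEnsemble(
        times=times, values=values, omega=omega,
        state_labels=meta.get("state_labels"),
        param_labels=meta.get("param_labels"),
        metadata=meta.get("metadata") or {},
    )


def write_grid(grid: ExtrinsicParamGrid, path) -> Path:
    """Write a full grid to one HDF5 container, one group per (omega, split)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["metadata"] = json.dumps(_jsonable(grid.metadata))
        for i, e in enumerate(grid.entries):
            g = fh.create_group(f"entry_{i:04d}")
            g.attrs["split"] = e.split
            _write_ensemble_h5(g, e.ensemble)
    return path


def read_grid(path) -> ExtrinsicParamGrid:
    path = Path(path)
    entries = []
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs.get("metadata", "{}"))
        for name in sorted(fh.keys()):
            g = fh[name]
            ens = _read_ensemble_h5(g)
            entries.append(GridEntry(omega=ens.omega, ensemble=ens,
                                     split=str(g.attrs["split"])))
    return ExtrinsicParamGrid(entries=entries, metadata=meta)


def split_grid(grid: ExtrinsicParamGrid, heldout_omegas: Iterable[Tuple[float, ...]],
               within_fraction: float, seed: int) -> ExtrinsicParamGrid:
    """Tag heldout omegas and split the rest per-trajectory into train/test.

    Every trajectory of a non-heldout ensemble lands in exactly one of
    train/test; heldout omegas contribute no training trajectories.  The
    split is deterministic for a fixed seed.
    """
    if not 0 < within_fraction <= 1:
        raise ValueError("within_fraction must be in (0, 1]")
    heldout = {_omega_key(np.atleast_1d(np.asarray(o, dtype=float))) for o in heldout_omegas}
    present = set(grid.omegas())
    missing = heldout - present
    if missing:
        raise ValueError(f"heldout omegas not present in grid: {sorted(missing)}")
    entries: List[GridEntry] = []
    for e in grid.entries:
        if e.omega_key in heldout:
            entries.append(GridEntry(e.omega, e.ensemble, "heldout"))
            continue
        n = e.ensemble.n_traj
        n_train = int(round(within_fraction * n))
        rng = np.random.default_rng(substream(seed, f"split:{e.omega_key}"))
        perm = rng.permutation(n)
        tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if tr.size:
            entries.append(GridEntry(e.omega, e.ensemble.subset(tr), "train"))
        if te.size:
            entries.append(GridEntry(e.omega, e.ensemble.subset(te), "test"))
    return ExtrinsicParamGrid(entries=entries, metadata=dict(grid.metadata))
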