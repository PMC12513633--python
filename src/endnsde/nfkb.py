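"""Stochastic NFkB signaling core with a pluggable latent subsystem.

The full signaling network is a 52-component system; here the components
for IkBa mRNA (u6), free cytoplasmic NFkB (u9) and nuclear NFkB (u10)
carry Brownian noise:

    du6  = (kbasal + kmax u52^n / (u52^n + K^n) - kdeg u6) dt + sigma1 dB1
    du9  = (kimp u9 - ka u2 u9 - kdegN u9 + v^-1 kexp u10
            + kd u4 + kphos u7) dt - sigma2 dB2
    du10 = (-kexp u10 - ka u3 u10 + v kimp u9 + kd u5) dt + sigma2 dB2

sigma1 is the IkBa-transcription noise intensity and sigma2 the NFkB
translocation noise intensity; the +/- sigma2 dB2 terms share one Wiener
increment, so translocation noise moves NFkB between compartments without
creating or destroying it.  The remaining 49 components are latent: they
evolve deterministically under a pluggable right-hand side whose kinetic
parameters come from configuration.  A bundled low-dimensional stable
surrogate (a damped negative-feedback loop driving u52) makes the module
fully exercisable; it is a synthetic stand-in, not the literature network.

State indexing is 0-based internally (u6 -> index 5, u9 -> 8, u10 -> 9);
the experimental readout is the total nuclear NFkB concentration u5 + u10.
Time is measured in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import ExtrinsicParamGrid, GridEntry, TrajectoryEnsemble, substream

__all__ = ["NFkBParams", "LatentRHS", "SyntheticLatentRHS", "sde_drift_core",
           "simulate", "representative_trajectory", "readout",
           "make_noise_grid", "make_experimental_standin",
           "IDX_U6", "IDX_U9", "IDX_U10", "IDX_U5", "STATE_DIM"]

STATE_DIM = 52
# 0-based indices of the named components
IDX_U2, IDX_U3, IDX_U4, IDX_U5 = 1, 2, 3, 4
IDX_U6, IDX_U7, IDX_U9, IDX_U10, IDX_U52 = 5, 6, 8, 9, 51
CORE = (IDX_U6, IDX_U9, IDX_U10)


@dataclass
class NFkBParams:
    """Kinetic constants of the noisy core plus the two noise intensities.

    The defaults are stand-in values chosen for a stable, damped-oscillatory
    representative cell with period on the hour scale; in applications they
    are supplied from a model/config file.
    """

    kbasal: float = 5e-4
    kmax: float = 0.015
    K_NFkB: float = 0.05
    n_NFkB: float = 3.0
    kdeg: float = 0.3
    kimp: float = 0.05
    kexp: float = 0.12
    ka_IkB_NFkB: float = 2.0
    kd_IkB_NFkB: float = 0.03
    kdeg_NFkB: float = 0.08
    kphos: float = 0.05
    v: float = 3.5
    sigma1: float = 0.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kbasal", "kmax", "K_NFkB", "kdeg", "kimp", "kexp",
                     "ka_IkB_NFkB", "kd_IkB_NFkB", "kdeg_NFkB", "kphos", "v",
                     "sigma1", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_NFkB < 1:
            raise ValueError("Hill coefficient must be >= 1")

    def replace_noise(self, sigma1: float, sigma2: float) -> "NFkBParams":
        from dataclasses import replace
        return replace(self, sigma1=sigma1, sigma2=sigma2)


def sde_drift_core(u: np.ndarray, params: NFkBParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drift of the three noisy components; ``u`` is (n, 52) or (52,).

    The Hill term saturates at kbasal + kmax and takes the half-maximum
    value at u52 = K_NFkB for any Hill exponent.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if np.any(u[:, IDX_U52] < 0):
        raise ValueError("negative Hill argument u52")
    p = params
    hill_num = u[:, IDX_U52] ** p.n_NFkB
    hill = np.where(hill_num > 0, hill_num / (hill_num + p.K_NFkB ** p.n_NFkB), 0.0)
    du6 = p.kbasal + p.kmax * hill - p.kdeg * u[:, IDX_U6]
    du9 = (p.kimp * u[:, IDX_U9]
           - p.ka_IkB_NFkB * u[:, IDX_U2] * u[:, IDX_U9]
           - p.kdeg_NFkB * u[:, IDX_U9]
           + p.kexp * u[:, IDX_U10] / p.v
           + p.kd_IkB_NFkB * u[:, IDX_U4]
           + p.kphos * u[:, IDX_U7])
    du10 = (-p.kexp * u[:, IDX_U10]
            - p.ka_IkB_NFkB * u[:, IDX_U3] * u[:, IDX_U10]
            + p.v * p.kimp * u[:, IDX_U9]
            + p.kd_IkB_NFkB * u[:, IDX_U5])
    return du6, du9, du10


class LatentRHS:
    """Interface for the deterministic dynamics of the 49 latent components.

    Implementations return a (n, 52) derivative array that is zero on the
    three core columns (those are advanced by the SDE core).
    """

    dimension: int = STATE_DIM - len(CORE)

    def __call__(self, u: np.ndarray, t: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class SyntheticLatentRHS(LatentRHS):
    """Synthetic stand-in latent subsystem (not the literature network).

    A minimal negative-feedback loop: nuclear NFkB (u10) activates the
    transcription-ready pool u52; IkBa mRNA (u6) is translated into
    cytoplasmic IkBa (u2), which is imported into the nucleus (u3), binds
    nuclear NFkB into the nuclear complex (u5), which is exported to the
    cytoplasmic complex (u4).  IKK activity (u7) relaxes under a constant
    stimulus.  All remaining components relax to their initial values and
    are dynamically inert.  Rates are per minute and give an hour-scale
    oscillation; the mRNA pool is kept small (fast turnover, high
    translation gain) so that both transcription and translocation noise
    visibly shape the u5 + u10 readout.
    """

    ktl: float = 5.0          # translation of u6 into u2 (small mRNA pool)
    kimp_IkB: float = 0.2     # nuclear import of IkBa
    delta2: float = 0.03
    delta3: float = 0.03
    ka: float = 2.0           # must match the core's association rate
    kd: float = 0.03
    kexp5: float = 0.15       # export of the nuclear complex
    kact: float = 0.5         # u10 -> u52 activation
    delta52: float = 0.15
    kstim: float = 0.02       # constant-dose stimulus feeding IKK from u4
    kphos: float = 0.05
    background_relax: float = 0.01
    baseline: Optional[np.ndarray] = None

    def __call__(self, u: np.ndarray, t: float) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        du = np.zeros_like(u)
        u2, u3, u4 = u[:, IDX_U2], u[:, IDX_U3], u[:, IDX_U4]
        u5, u6, u7 = u[:, IDX_U5], u[:, IDX_U6], u[:, IDX_U7]
        u9, u10, u52 = u[:, IDX_U9], u[:, IDX_U10], u[:, IDX_U52]
        du[:, IDX_U2] = self.ktl * u6 - self.kimp_IkB * u2 - self.delta2 * u2 - self.ka * u2 * u9
        du[:, IDX_U3] = self.kimp_IkB * u2 - self.ka * u3 * u10 - self.delta3 * u3
        du[:, IDX_U4] = self.ka * u2 * u9 + self.kexp5 * u5 - self.kd * u4 - self.kstim * u4
        du[:, IDX_U5] = self.ka * u3 * u10 - self.kexp5 * u5 - self.kd * u5
        du[:, IDX_U7] = self.kstim * u4 - self.kphos * u7
        du[:, IDX_U52] = self.kact * u10 - self.delta52 * u52
        baseline = self.baseline if self.baseline is not None else 0.0
        inert = np.ones(STATE_DIM, dtype=bool)
        inert[[IDX_U2, IDX_U3, IDX_U4, IDX_U5, IDX_U6, IDX_U7,
               IDX_U9, IDX_U10, IDX_U52]] = False
        du[:, inert] = -self.background_relax * (u[:, inert] - baseline)
        for idx in CORE:
            du[:, idx] = 0.0
        return du


def default_u0() -> np.ndarray:
    """Resting-cell initial state: NFkB sequestered in the cytoplasmic
    complex, stimulus just delivered (IKK pool nonzero)."""
    u0 = np.full(STATE_DIM, 0.05)
    u0[IDX_U2] = 0.10
    u0[IDX_U3] = 0.01
    u0[IDX_U4] = 1.00
    u0[IDX_U5] = 0.01
    u0[IDX_U6] = 0.01
    u0[IDX_U7] = 0.20
    u0[IDX_U9] = 0.02
    u0[IDX_U10] = 0.02
    u0[IDX_U52] = 0.01
    return u0


def default_times(n_points: int = 31, spacing_min: float = 5.0) -> np.ndarray:
    return np.arange(n_points) * spacing_min


def simulate(params: NFkBParams, latent: Optional[LatentRHS], u0, times,
             n_traj: int, seed: int, clamp: bool = True,
             substeps: int = 25) -> TrajectoryEnsemble:
    """Euler--Maruyama on the 52-D system; noise only on (u6, u9, u10).

    The u9/u10 translocation noise uses a single shared Wiener increment
    with opposite signs, so its contribution to d(u9 + u10) cancels
    exactly.  Concentrations are reflected at zero after each step
    (``clamp``); the number of clamped entries is recorded in metadata.

    The output grid (typically 5-minute frames) is much coarser than the
    stability limit of the fastest reactions, so each frame interval is
    integrated with ``substeps`` internal Euler--Maruyama steps.
    """
    latent = latent if latent is not None else SyntheticLatentRHS()
    times = np.asarray(times, dtype=float).ravel()
    u0 = np.asarray(u0, dtype=float)
    if u0.ndim == 1:
        u0 = np.broadcast_to(u0, (n_traj, u0.size)).copy()
    if u0.shape[1] != STATE_DIM or np.any(u0 < 0):
        raise ValueError(f"u0 must be nonnegative with {STATE_DIM} components")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    rng = np.random.default_rng(seed)
    T = times.size
    out = np.empty((n_traj, T, STATE_DIM))
    out[:, 0] = u0
    u = u0.copy()
    n_clamped = 0
    for j in range(T - 1):
        dt = (times[j + 1] - times[j]) / substeps
        sq = np.sqrt(dt)
        for s in range(substeps):
            du = latent(u, times[j] + s * dt)
            du6, du9, du10 = sde_drift_core(u, params)
            du[:, IDX_U6] = du6
            du[:, IDX_U9] = du9
            du[:, IDX_U10] = du10
            if not np.all(np.isfinite(du)):
                raise FloatingPointError(f"non-finite right-hand side at step {j}")
            u = u + du * dt
            db1 = rng.normal(0.0, sq, size=n_traj)
            db2 = rng.normal(0.0, sq, size=n_traj)
            u[:, IDX_U6] += params.sigma1 * db1
            u[:, IDX_U9] -= params.sigma2 * db2
            u[:, IDX_U10] += params.sigma2 * db2
            if clamp:
                neg = u < 0
                n_clamped += int(neg.sum())
                np.maximum(u, 0.0, out=u)
        out[:, j + 1] = u
    return TrajectoryEnsemble(
        times=times, values=out, omega=np.array([params.sigma1, params.sigma2]),
        state_labels=[f"u{i + 1}" for i in range(STATE_DIM)],
        param_labels=["sigma1", "sigma2"],
        metadata={"seed": int(seed), "n_clamped": n_clamped,
                  "readout": "u5+u10"})


def representative_trajectory(params: NFkBParams = None,
                              latent: Optional[LatentRHS] = None,
                              u0=None, times=None) -> TrajectoryEnsemble:
    """Deterministic representative-cell trajectory (noise switched off)."""
    params = (params or NFkBParams()).replace_noise(0.0, 0.0)
    u0 = u0 if u0 is not None else default_u0()
    times = times if times is not None else default_times()
    return simulate(params, latent, u0, times, n_traj=1, seed=0)


def readout(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Total nuclear NFkB concentration u5 + u10, shape (n_traj, n_times)."""
    return ensemble.values[:, :, IDX_U5] + ensemble.values[:, :, IDX_U10]


def default_noise_axes() -> Tuple[np.ndarray, np.ndarray]:
    lg1 = np.round(np.arange(-3.2, -2.2 + 1e-9, 0.1), 10)
    lg2 = np.round(np.arange(-2.5, -1.5 + 1e-9, 0.1), 10)
    return lg1, lg2


def make_noise_grid(ranges: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
                    seed: int = 0, n_traj: int = 50,
                    params: Optional[NFkBParams] = None,
                    latent: Optional[LatentRHS] = None,
                    u0=None, times=None) -> ExtrinsicParamGrid:
    """Ensembles on the (sigma1, sigma2) noise-intensity grid.

    Default axes: 11 log-spaced values per axis, lg sigma1 in [-3.2, -2.2]
    and lg sigma2 in [-2.5, -1.5] (121 combinations), anchoring the two
    example corners (10^-3.2, 10^-2.5) and (10^-2.2, 10^-1.5).
    """
    if ranges is None:
        lg1, lg2 = default_noise_axes()
    else:
        lg1, lg2 = (np.asarray(r, dtype=float) for r in ranges)
    params = params or NFkBParams()
    latent = latent or SyntheticLatentRHS()
    u0 = u0 if u0 is not None else default_u0()
    times = times if times is not None else default_times()
    entries = []
    for a in np.atleast_1d(lg1):
        for b in np.atleast_1d(lg2):
            s1, s2 = 10.0**a, 10.0**b
            p = params.replace_noise(s1, s2)
            ens = simulate(p, latent, u0, times, n_traj,
                           substream(seed, f"nfkb:{a:.3f}:{b:.3f}"))
            entries.append(GridEntry(ens.omega, ens, "train"))
    return ExtrinsicParamGrid(entries=entries, metadata={
        "system": "nfkb", "seed": int(seed),
        "lg_sigma1": [float(v) for v in np.atleast_1d(lg1)],
        "lg_sigma2": [float(v) for v in np.atleast_1d(lg2)]})


def make_experimental_standin(n_cells: int, params_grid: Sequence[Tuple[float, float]],
                              latent: Optional[LatentRHS] = None, seed: int = 0,
                              params: Optional[NFkBParams] = None,
                              u0=None, times=None) -> TrajectoryEnsemble:
    """Synthetic emulation of live-cell NFkB recordings (stand-in data).

    Scalar readout u5 + u10 on 31 frames at 5-minute spacing; each cell is
    drawn from a uniform mixture over the supplied (sigma1, sigma2) noise
    levels.  The per-cell ground-truth noise intensities are stored in
    metadata for validating the inference workflow — real recordings do
    not carry them.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    params = params or NFkBParams()
    latent = latent or SyntheticLatentRHS()
    u0 = u0 if u0 is not None else default_u0()
    times = times if times is not None else default_times()
    rng = np.random.default_rng(substream(seed, "standin-mixture"))
    levels = list(params_grid)
    assign = rng.integers(0, len(levels), size=n_cells)
    vals = np.empty((n_cells, np.asarray(times).size, 1))
    true_noise = np.empty((n_cells, 2))
    for li, (s1, s2) in enumerate(levels):
        rows = np.flatnonzero(assign == li)
        if rows.size == 0:
            continue
        ens = simulate(params.replace_noise(s1, s2), latent, u0, times,
                       rows.size, substream(seed, f"standin:{li}"))
        vals[rows, :, 0] = readout(ens)
        true_noise[rows] = (s1, s2)
    return TrajectoryEnsemble(
        times=np.asarray(times, dtype=float), values=vals, omega=np.zeros(1),
        state_labels=["u5+u10"],
        metadata={"seed": int(seed), "readout": "u5+u10",
                  "true_noise_per_cell": true_noise.tolist(),
                  "synthetic_standin": True})
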