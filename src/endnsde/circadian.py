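"""Damped-oscillator circadian SDE and its dataset factories.

A minimal model of *per* gene expression: x (mRNA) and y (protein) follow a
linear rotation-damping drift

    dx = (-alpha x - beta y) dt + xi_x1 dB1 + xi_x2 dB2
    dy = ( beta x - alpha y) dt + xi_y1 dB1 + xi_y2 dB2

whose noise-free solution spirals into the stable origin; sustained
single-cell rhythms are therefore noise-induced.  Three diffusion forms are
supported (constant, Langevin |x|-scaled, linear signed), each with a noise
intensity sigma0 and a cross-correlation coefficient c, plus a fourth,
diagonal multiplicative form in which per-cell coefficients (k1, k2)
modulate the noise intensity around sigma0 with extrinsic strength sigma1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .data import ExtrinsicParamGrid, GridEntry, TrajectoryEnsemble, substream
from .model import SDEField, em_integrate

__all__ = ["CircadianParams", "diffusion_matrix", "drift", "simulate",
           "make_grid_dataset", "make_percell_dataset", "field_for_form",
           "DEFAULT_ALPHA", "DEFAULT_BETA"]

DEFAULT_ALPHA = 0.19
DEFAULT_BETA = 0.21
FORMS = ("const", "langevin", "linear", "percell")


@dataclass
class CircadianParams:
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    diffusion_form: str = "const"
    sigma0: float = 0.1
    c: float = 0.2
    sigma1: float = 0.0
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("noise intensities must be nonnegative")
        if self.diffusion_form not in FORMS:
            raise ValueError(f"diffusion_form must be one of {FORMS}")


def drift(params: CircadianParams, x, y):
    """Rotation-damping drift (-a x - b y, b x - a y), vectorized."""
    return (-params.alpha * x - params.beta * y,
            params.beta * x - params.alpha * y)


def diffusion_matrix(params: CircadianParams, x: float, y: float) -> np.ndarray:
    """2x2 diffusion coefficient matrix at state (x, y) for the three
    correlated forms.  The linear form keeps the signed x and y on the
    diagonal with |.| only on the off-diagonal entries — the sign asymmetry
    is part of the model."""
    s0, c = params.sigma0, params.c
    if params.diffusion_form == "const":
        return s0 * np.array([[1.0, c], [c, 1.0]])
    if params.diffusion_form == "langevin":
        return s0 * np.array([[abs(x), c * abs(y)], [c * abs(x), abs(y)]])
    if params.diffusion_form == "linear":
        return s0 * np.array([[x, c * abs(y)], [c * abs(x), y]])
    raise ValueError(
        "percell uses its own diagonal diffusion ((sigma0+sigma1*k1)x, "
        "(sigma0+sigma1*k2)y); use field_for_form('percell')")


def _diffusion_batch(params: CircadianParams, states: np.ndarray,
                     sigma0: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized diffusion over (n, 2) states; sigma0/c broadcast per row."""
    x, y = states[:, 0], states[:, 1]
    n = states.shape[0]
    g = np.empty((n, 2, 2))
    form = params.diffusion_form
    if form == "const":
        one = np.ones(n)
        g[:, 0, 0] = one
        g[:, 0, 1] = c
        g[:, 1, 0] = c
        g[:, 1, 1] = one
    elif form == "langevin":
        g[:, 0, 0] = np.abs(x)
        g[:, 0, 1] = c * np.abs(y)
        g[:, 1, 0] = c * np.abs(x)
        g[:, 1, 1] = np.abs(y)
    elif form == "linear":
        g[:, 0, 0] = x
        g[:, 0, 1] = c * np.abs(y)
        g[:, 1, 0] = c * np.abs(x)
        g[:, 1, 1] = y
    else:
        raise ValueError(form)
    return sigma0[:, None, None] * g if np.ndim(sigma0) else sigma0 * g


def field_for_form(form: str, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                   sigma0: float = 0.1, sigma1: float = 0.0) -> SDEField:
    """Ground-truth SDE field whose omega argument carries the stratum.

    For the correlated forms omega = (sigma0, c); for the percell form omega =
    (k1, k2) with (sigma0, sigma1) fixed at construction.  Used both for
    simulation and as the reference field in error metrics.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")

    def _drift(states: np.ndarray, omega) -> np.ndarray:
        x, y = states[:, 0], states[:, 1]
        return np.stack([-alpha * x - beta * y, beta * x - alpha * y], axis=1)

    if form == "percell":
        def _diff(states: np.ndarray, omega) -> np.ndarray:
            om = np.atleast_2d(np.asarray(omega, dtype=float))
            k1 = om[..., 0]
            k2 = om[..., 1]
            n = states.shape[0]
            g = np.zeros((n, 2, 2))
            g[:, 0, 0] = (sigma0 + sigma1 * k1) * states[:, 0]
            g[:, 1, 1] = (sigma0 + sigma1 * k2) * states[:, 1]
            return g
    else:
        def _diff(states: np.ndarray, omega) -> np.ndarray:
            om = np.atleast_2d(np.asarray(omega, dtype=float))
            s0 = om[..., 0]
            c = om[..., 1]
            params = CircadianParams(alpha=alpha, beta=beta, diffusion_form=form)
            s0b = np.broadcast_to(s0, (states.shape[0],))
            cb = np.broadcast_to(c, (states.shape[0],))
            return _diffusion_batch(params, states, s0b, cb)

    return SDEField(state_dim=2, param_dim=2, noise_dim=2,
                    drift=_drift, diffusion=_diff)


def simulate(params: CircadianParams, x0: Tuple[float, float], times, n_traj: int,
             seed: int) -> TrajectoryEnsemble:
    """Euler--Maruyama ensemble from the ground-truth circadian SDE.

    omega is recorded as (sigma0, c) for the correlated forms and (k1, k2)
    for the percell form; two independent Wiener streams drive each trajectory.
    """
    if params.diffusion_form == "percell":
        fld = field_for_form("percell", params.alpha, params.beta,
                             sigma0=params.sigma0, sigma1=params.sigma1)
        omega = np.array([params.k1, params.k2])
        labels = ["k1", "k2"]
        meta = {"sigma0": params.sigma0, "sigma1": params.sigma1,
                "diffusion_form": "percell"}
    else:
        fld = field_for_form(params.diffusion_form, params.alpha, params.beta)
        omega = np.array([params.sigma0, params.c])
        labels = ["sigma0", "c"]
        meta = {"diffusion_form": params.diffusion_form}
    ens = em_integrate(fld, np.asarray(x0, dtype=float), omega, times, n_traj, seed,
                       metadata=meta)
    ens.state_labels = ["x", "y"]
    ens.param_labels = labels
    return ens


def default_times(dt: float = 0.02, horizon: float = 1.0) -> np.ndarray:
    return np.linspace(0.0, horizon, int(round(horizon / dt)) + 1)


def make_grid_dataset(form: str, seed: int, n_traj: int = 50,
                      dt: float = 0.02, horizon: float = 1.0,
                      alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                      x0: Tuple[float, float] = (0.0, 1.0)) -> ExtrinsicParamGrid:
    """The 25-point (sigma0, c) study grid for one diffusion form.

    sigma0 in {0.10, 0.15, 0.20, 0.25, 0.30}, c in {0.2, 0.4, 0.6, 0.8, 1.0};
    50 trajectories per combination on t in [0, 1] from x0 = (0, 1).
    """
    if form not in ("const", "langevin", "linear"):
        raise ValueError("form must be const, langevin or linear")
    times = default_times(dt, horizon)
    entries = []
    for i in range(5):
        for j in range(5):
            s0 = 0.1 + 0.05 * i
            c = 0.2 + 0.2 * j
            p = CircadianParams(alpha=alpha, beta=beta, diffusion_form=form,
                                sigma0=s0, c=c)
            ens = simulate(p, x0, times, n_traj,
                           substream(seed, f"circadian:{form}:{i}:{j}"))
            entries.append(GridEntry(ens.omega, ens, "train"))
    return ExtrinsicParamGrid(entries=entries, metadata={
        "system": "circadian", "form": form, "alpha": alpha, "beta": beta,
        "x0": list(x0), "seed": int(seed)})


def make_percell_dataset(sigma0: float, sigma1: float, seed: int, n_traj: int = 50,
                      dt: float = 0.02, horizon: float = 1.0,
                      alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                      x0: Tuple[float, float] = (0.0, 1.0)) -> ExtrinsicParamGrid:
    """25 groups keyed by per-cell coefficients (k1, k2) in {0, ±0.5, ±1}^2."""
    if sigma0 < 0 or sigma1 < 0:
        raise ValueError("sigma0 and sigma1 must be nonnegative")
    times = default_times(dt, horizon)
    ks = (-1.0, -0.5, 0.0, 0.5, 1.0)
    entries = []
    for k1 in ks:
        for k2 in ks:
            p = CircadianParams(alpha=alpha, beta=beta, diffusion_form="percell",
                                sigma0=sigma0, sigma1=sigma1, k1=k1, k2=k2)
            ens = simulate(p, x0, times, n_traj,
                           substream(seed, f"circadian:percell:{k1}:{k2}"))
            entries.append(GridEntry(ens.omega, ens, "train"))
    return ExtrinsicParamGrid(entries=entries, metadata={
        "system": "circadian", "form": "percell", "alpha": alpha, "beta": beta,
        "sigma0": sigma0, "sigma1": sigma1, "x0": list(x0), "seed": int(seed)})
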