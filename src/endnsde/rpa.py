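"""Exact Gillespie simulation of multi-mode RPA binding on an ssDNA lattice.

Replication protein A binds single-stranded DNA in a 20-nucleotide
footprint (rate k1 per eligible start position), unbinds at rate k_-1,
extends into a 30-nt footprint when the 10 nt immediately downstream are
free (rate k2), and reverts to the 20-nt mode at rate k_-2.  Occupied
nucleotides exclude further binding, so the process is a continuous-time
Markov chain on disjoint-footprint lattice configurations — a random
sequential adsorption process with an extension reaction.

The observable is the pair of filling fractions x1 = 20 N20 / L and
x2 = 30 N30 / L sampled onto a fixed output grid by last-value
interpolation.  The simulator is exact (exponential waiting times, event
choice proportional to propensity); propensities are recomputed from the
configuration at every event.

k1 semantics: the printed rate is per eligible 20-mer start position, so
free RPA acts as an unlimited reservoir (total binding propensity =
k1 x number of eligible starts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .data import ExtrinsicParamGrid, GridEntry, TrajectoryEnsemble, substream

__all__ = ["RPAParams", "LatticeState", "enumerate_events", "ssa_run",
           "make_k2_dataset"]


@dataclass
class RPAParams:
    k1: float = 1e-3      # 20nt-mode binding, s^-1 per eligible start
    k_1: float = 1e-6     # 20nt-mode unbinding, s^-1
    k2: float = 1e-3      # 20 -> 30 nt extension, s^-1
    k_2: float = 1e-6     # 30 -> 20 nt reversion, s^-1
    L: int = 5000         # lattice length, nt
    horizon: float = 5000.0  # simulated time, s
    n_grid: int = 51      # output time points (uniform on [0, horizon])

    def __post_init__(self) -> None:
        if min(self.k1, self.k_1, self.k2, self.k_2) < 0:
            raise ValueError("rates must be nonnegative")
        if self.L < 20:
            raise ValueError("lattice must hold at least one 20-nt footprint")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_grid)


@dataclass
class LatticeState:
    """Occupancy configuration: disjoint (start, mode) footprints, 0-based,
    half-open intervals [start, start + mode) within [0, L)."""

    L: int
    bound_proteins: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bound_proteins = sorted(self.bound_proteins)
        prev_end = 0
        for start, mode in self.bound_proteins:
            if mode not in (20, 30):
                raise ValueError(f"mode must be 20 or 30, got {mode}")
            if start < prev_end or start + mode > self.L:
                raise ValueError("footprints overlap or exceed the lattice")
            prev_end = start + mode
        n20 = sum(1 for _, m in self.bound_proteins if m == 20)
        n30 = len(self.bound_proteins) - n20
        assert 20 * n20 + 30 * n30 <= self.L

    def filling_fractions(self) -> Tuple[float, float]:
        n20 = sum(1 for _, m in self.bound_proteins if m == 20)
        n30 = len(self.bound_proteins) - n20
        return 20.0 * n20 / self.L, 30.0 * n30 / self.L


def enumerate_events(state: LatticeState, params: RPAParams):
    """All possible events with their propensities, re-derived from occupancy.

    Returns a list of (kind, payload, propensity) with kind in
    {"bind", "unbind", "extend", "revert"}; bind payloads are start
    positions, the others index into ``state.bound_proteins``.  An empty
    list is valid (absorbing frozen configuration).
    """
    events = []
    prot = state.bound_proteins
    # eligible 20-mer starts inside every free gap
    bounds = [0] + [s + m for s, m in prot]
    nexts = [s for s, _ in prot] + [state.L]
    if params.k1 > 0:
        for lo, hi in zip(bounds, nexts):
            for s in range(lo, hi - 19):
                events.append(("bind", s, params.k1))
    for i, (s, m) in enumerate(prot):
        if m == 20:
            if params.k_1 > 0:
                events.append(("unbind", i, params.k_1))
            right = prot[i + 1][0] if i + 1 < len(prot) else state.L
            if params.k2 > 0 and s + 30 <= right:
                events.append(("extend", i, params.k2))
        else:
            if params.k_2 > 0:
                events.append(("revert", i, params.k_2))
    return events


# ---------------------------------------------------------------------------
# fast SSA core (numba-jitted when available; same code runs in pure python)
# ---------------------------------------------------------------------------

def _ssa_core(L, k1, km1, k2, km2, grid, horizon, seed):  # pragma: no cover
    np.random.seed(seed)
    for _ in range(8):  # warm up the generator state
        np.random.random()
    T = grid.shape[0]
    out = np.zeros((T, 2))
    maxP = L // 20 + 1
    starts = np.zeros(maxP, dtype=np.int64)
    modes = np.zeros(maxP, dtype=np.int64)
    n = 0
    t = 0.0
    gi = 0
    while True:
        # propensities, recomputed from the configuration
        elig = 0
        n20 = 0
        n30 = 0
        n_ext = 0
        prev_end = 0
        for i in range(n):
            gap = starts[i] - prev_end
            if gap >= 20:
                elig += gap - 19
            prev_end = starts[i] + modes[i]
        gap = L - prev_end
        if gap >= 20:
            elig += gap - 19
        for i in range(n):
            if modes[i] == 20:
                n20 += 1
                right = starts[i + 1] if i + 1 < n else L
                if starts[i] + 30 <= right:
                    n_ext += 1
            else:
                n30 += 1
        a_bind = k1 * elig
        a_unbind = km1 * n20
        a_ext = k2 * n_ext
        a_rev = km2 * n30
        a_tot = a_bind + a_unbind + a_ext + a_rev
        x1 = 20.0 * n20 / L
        x2 = 30.0 * n30 / L
        if a_tot <= 0.0:
            while gi < T:
                out[gi, 0] = x1
                out[gi, 1] = x2
                gi += 1
            break
        t_new = t - np.log(np.random.random()) / a_tot
        while gi < T and grid[gi] < t_new:
            out[gi, 0] = x1
            out[gi, 1] = x2
            gi += 1
        if gi >= T or t_new > horizon:
            while gi < T:
                out[gi, 0] = x1
                out[gi, 1] = x2
                gi += 1
            break
        t = t_new
        u = np.random.random() * a_tot
        if u < a_bind:
            rank = int(u / k1)
            if rank >= elig:
                rank = elig - 1
            prev_end = 0
            pos = -1
            for i in range(n + 1):
                nxt = starts[i] if i < n else L
                gap = nxt - prev_end
                e_g = gap - 19 if gap >= 20 else 0
                if rank < e_g:
                    pos = prev_end + rank
                    break
                rank -= e_g
                if i < n:
                    prev_end = starts[i] + modes[i]
            # insert keeping starts sorted
            ins = 0
            while ins < n and starts[ins] < pos:
                ins += 1
            for j in range(n, ins, -1):
                starts[j] = starts[j - 1]
                modes[j] = modes[j - 1]
            starts[ins] = pos
            modes[ins] = 20
            n += 1
        elif u < a_bind + a_unbind:
            rank = int((u - a_bind) / km1)
            if rank >= n20:
                rank = n20 - 1
            cnt = -1
            for i in range(n):
                if modes[i] == 20:
                    cnt += 1
                    if cnt == rank:
                        for j in range(i, n - 1):
                            starts[j] = starts[j + 1]
                            modes[j] = modes[j + 1]
                        n -= 1
                        break
        elif u < a_bind + a_unbind + a_ext:
            rank = int((u - a_bind - a_unbind) / k2)
            if rank >= n_ext:
                rank = n_ext - 1
            cnt = -1
            for i in range(n):
                if modes[i] == 20:
                    right = starts[i + 1] if i + 1 < n else L
                    if starts[i] + 30 <= right:
                        cnt += 1
                        if cnt == rank:
                            modes[i] = 30
                            break
        else:
            rank = int((u - a_bind - a_unbind - a_ext) / km2)
            if rank >= n30:
                rank = n30 - 1
            cnt = -1
            for i in range(n):
                if modes[i] == 30:
                    cnt += 1
                    if cnt == rank:
                        modes[i] = 20
                        break
    return out


try:  # the jitted core is a drop-in; the python path is the reference
    from numba import njit

    _ssa_core_fast = njit(cache=False)(_ssa_core)
except Exception:  # pragma: no cover
    _ssa_core_fast = _ssa_core


def ssa_run(params: RPAParams, seed: int, use_numba: bool = True) -> TrajectoryEnsemble:
    """One exact SSA trajectory of (x1, x2) sampled on ``params.grid``.

    x1 and x2 are the filling fractions of the lattice by 20nt- and
    30nt-mode footprints; x1 + x2 <= 1 at all times.  Zero total propensity
    freezes the state until the horizon (not an error).
    """
    core = _ssa_core_fast if use_numba else _ssa_core
    # scramble the seed: sequential raw seeds give correlated first draws
    seed32 = int(np.random.SeedSequence(int(seed)).generate_state(1)[0] % (2**31 - 1))
    vals = core(params.L, params.k1, params.k_1, params.k2, params.k_2,
                params.grid, params.horizon, seed32)
    return TrajectoryEnsemble(
        times=params.grid, values=vals[None, :, :],
        omega=np.array([np.log10(params.k2) if params.k2 > 0 else -np.inf]),
        state_labels=["x1", "x2"], param_labels=["lg_k2"],
        metadata={"seed": int(seed), "L": params.L})


def make_k2_dataset(params_base: RPAParams = None, seed: int = 0,
                    n_traj: int = 100, k2_exponents=None,
                    normalize_time: bool = True,
                    train_fraction: float = 0.5) -> ExtrinsicParamGrid:
    """The conversion-rate sweep: ensembles at lg k2 in {-4.0, ..., -1.5}.

    100 trajectories per k2 value, the first half tagged train and the
    second half test.  With ``normalize_time`` the grid is rescaled to
    [0, 1] (units of the horizon) so losses are on the scale used for all
    other systems.
    """
    params_base = params_base or RPAParams()
    if k2_exponents is None:
        k2_exponents = [-4.0 + j / 10 for j in range(26)]
    entries = []
    for lg in k2_exponents:
        p = RPAParams(k1=params_base.k1, k_1=params_base.k_1, k2=10.0**lg,
                      k_2=params_base.k_2, L=params_base.L,
                      horizon=params_base.horizon, n_grid=params_base.n_grid)
        vals = np.empty((n_traj, p.n_grid, 2))
        for i in range(n_traj):
            run = ssa_run(p, substream(seed, f"rpa:{lg:.3f}:{i}"))
            vals[i] = run.values[0]
        times = p.grid / p.horizon if normalize_time else p.grid
        omega = np.array([lg])
        n_train = int(round(train_fraction * n_traj))
        common = dict(times=times, omega=omega, state_labels=["x1", "x2"],
                      param_labels=["lg_k2"],
                      metadata={"L": p.L, "horizon_s": p.horizon,
                                "time_unit": "horizon" if normalize_time else "s"})
        if n_train:
            entries.append(GridEntry(omega, TrajectoryEnsemble(
                values=vals[:n_train], **common), "train"))
        if n_train < n_traj:
            entries.append(GridEntry(omega, TrajectoryEnsemble(
                values=vals[n_train:], **common), "test"))
    return ExtrinsicParamGrid(entries=entries, metadata={
        "system": "rpa", "seed": int(seed), "k1": params_base.k1,
        "k_1": params_base.k_1, "k_2": params_base.k_2, "L": params_base.L,
        "horizon_s": params_base.horizon})
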