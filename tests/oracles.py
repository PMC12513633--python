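"""Independent brute-force oracles shared by the lattice-SSA tests."""

import numpy as np
from scipy import stats


def exponential_cell_chisquare(cells, grid, rate):
    """Chi-square of observed grid-cell indices of a censored Exp(rate)
    first-event time against the exact cell probabilities."""
    cells = np.asarray(cells)
    T = grid.size
    edges = np.concatenate([grid, [np.inf]])
    cdf = 1 - np.exp(-rate * edges)
    probs = np.diff(np.concatenate([[0.0], cdf]))  # P(cell j), j = 0..T
    counts = np.bincount(cells, minlength=T + 1).astype(float)
    # merge low-expectation bins into the tail for chi-square validity
    expected = probs * cells.size
    keep = expected >= 5
    obs = np.concatenate([counts[keep], [counts[~keep].sum()]])
    exp = np.concatenate([expected[keep], [expected[~keep].sum()]])
    return stats.chisquare(obs, exp * obs.sum() / exp.sum())


def rsa_jamming_oracle(L, n_runs, rng):
    """Brute-force random sequential adsorption of 20-mers: repeatedly pick a
    uniformly random eligible start until jamming; return mean coverage.
    Independent of the SSA code path (direct placement sampling)."""
    covs = []
    for _ in range(n_runs):
        occupied = np.zeros(L, dtype=bool)
        while True:
            free = ~occupied
            # eligible starts: 20 consecutive free sites
            run = np.convolve(free.astype(int), np.ones(20, dtype=int), "valid")
            starts = np.flatnonzero(run == 20)
            if starts.size == 0:
                break
            s = starts[rng.integers(starts.size)]
            occupied[s:s + 20] = True
        covs.append(occupied.mean())
    return float(np.mean(covs))
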