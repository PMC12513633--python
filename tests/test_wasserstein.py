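"""W2 kernel: exhaustive-coupling oracles, closed forms, gradients."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endnsde.data import ExtrinsicParamGrid, GridEntry, TrajectoryEnsemble
from endnsde.wasserstein import (extrinsic_loss, marginal_w2_squared,
                                 marginal_w2_squared_grad, temporal_w2_squared)


def brute_force_w2(a, b):
    """Minimum mean squared pairing cost over all n! bijective couplings."""
    n = len(a)
    return min(
        sum((a[i] - b[p[i]]) ** 2 for i in range(n)) / n
        for p in itertools.permutations(range(n))
    )


@pytest.mark.parametrize("a,b,expected", [
    ([0.3, 1.7], [0.3, 1.7], 0.0),
    ([0.0], [1.0], 1.0),
    ([0.0, 2.0], [1.0, 3.0], 1.0),  # sorted pairing (1+1)/2 beats crossed (9+1)/2
])
def test_marginal_known_values(a, b, expected):
    assert marginal_w2_squared(a, b) == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=5).flatmap(
    lambda a: st.tuples(st.just(a),
                        st.lists(st.floats(-50, 50),
                                 min_size=len(a), max_size=len(a)))))
def test_marginal_matches_exhaustive_coupling(ab):
    a, b = ab
    assert marginal_w2_squared(a, b) == pytest.approx(brute_force_w2(a, b), abs=1e-9)


def test_marginal_symmetric_and_zero_iff_equal(rng):
    a = rng.normal(size=7)
    b = rng.normal(size=7)
    assert marginal_w2_squared(a, b) == pytest.approx(marginal_w2_squared(b, a))
    assert marginal_w2_squared(a, np.random.permutation(a)) == 0.0
    assert marginal_w2_squared(a, b) > 0


def test_marginal_gaussian_closed_form():
    """W2^2 between two Gaussians is (m1-m2)^2 + (s1-s2)^2."""
    rng = np.random.default_rng(7)
    n = 10**5
    a = rng.normal(0.0, 1.0, size=n)
    b = rng.normal(2.0, 1.0, size=n)
    assert marginal_w2_squared(a, b) == pytest.approx(4.0, rel=0.02)


def test_marginal_triangle_inequality(rng):
    for _ in range(20):
        a, b, c = (rng.normal(scale=rng.uniform(0.5, 2), size=6) for _ in range(3))
        wab = np.sqrt(marginal_w2_squared(a, b))
        wbc = np.sqrt(marginal_w2_squared(b, c))
        wac = np.sqrt(marginal_w2_squared(a, c))
        assert wac <= wab + wbc + 1e-12


def test_marginal_gradient_matches_finite_differences(rng):
    a = rng.normal(size=6)
    b = rng.normal(size=6)
    grad = marginal_w2_squared_grad(a, b)
    eps = 1e-6
    for k in range(6):
        bp, bm = b.copy(), b.copy()
        bp[k] += eps
        bm[k] -= eps
        fd = (marginal_w2_squared(a, bp) - marginal_w2_squared(a, bm)) / (2 * eps)
        assert grad[k] == pytest.approx(fd, abs=1e-5)


def test_marginal_rejects_bad_input():
    with pytest.raises(ValueError):
        marginal_w2_squared([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        marginal_w2_squared([], [])


# ---------------------------------------------------------------------------

def _ens(times, values, omega=(0.0,)):
    return TrajectoryEnsemble(times=np.asarray(times, dtype=float),
                              values=np.asarray(values, dtype=float),
                              omega=np.asarray(omega))


def test_temporal_identical_is_zero(small_ensemble):
    assert temporal_w2_squared(small_ensemble, small_ensemble) == 0.0


def test_temporal_constant_offset_integrates_to_c2T():
    """Observed ≡ 0 and predicted ≡ c give c^2 at every time, integral c^2*T."""
    times = np.linspace(0, 2.0, 21)
    obs = _ens(times, np.zeros((3, 21, 1)))
    c = 0.7
    pred = _ens(times, np.full((3, 21, 1), c))
    assert temporal_w2_squared(obs, pred) == pytest.approx(c**2 * 2.0)


def test_temporal_matches_per_time_brute_force():
    times = [0.0, 0.4, 1.0]
    obs = _ens(times, [[[0.1], [0.5], [1.0]], [[0.2], [0.9], [0.4]]])
    pred = _ens(times, [[[0.0], [0.7], [0.8]], [[0.3], [0.2], [1.1]]])
    expected = 0.0
    w = [0.4, 0.6, 0.0]  # left-Riemann weights
    for j, wj in enumerate(w):
        a = obs.values[:, j, 0]
        b = pred.values[:, j, 0]
        costs = []
        for p in itertools.permutations(range(2)):
            costs.append(sum((a[i] - b[p[i]]) ** 2 for i in range(2)) / 2)
        expected += wj * min(costs)
    assert temporal_w2_squared(obs, pred) == pytest.approx(expected)


def test_temporal_invariant_to_trajectory_relabeling(rng):
    times = np.linspace(0, 1, 6)
    obs = _ens(times, rng.normal(size=(5, 6, 2)))
    pred = _ens(times, rng.normal(size=(5, 6, 2)))
    shuffled = _ens(times, pred.values[rng.permutation(5)])
    assert temporal_w2_squared(obs, pred) == pytest.approx(
        temporal_w2_squared(obs, shuffled))


def test_temporal_rejects_mismatched_grids(small_ensemble):
    other = _ens([0.0, 0.6, 1.0], small_ensemble.values, omega=(0.1, 0.2))
    with pytest.raises(ValueError):
        temporal_w2_squared(small_ensemble, other)


# ---------------------------------------------------------------------------

def _grid(entries):
    return ExtrinsicParamGrid(entries=[
        GridEntry(e.omega, e, "train") for e in entries])


def test_extrinsic_loss_additivity(rng):
    times = np.linspace(0, 1, 5)
    obs, pred = [], []
    for k in range(3):
        obs.append(_ens(times, rng.normal(size=(4, 5, 1)), omega=(float(k),)))
        pred.append(_ens(times, rng.normal(size=(4, 5, 1)), omega=(float(k),)))
    report = extrinsic_loss(_grid(obs), _grid(pred))
    singles = [temporal_w2_squared(o, p) for o, p in zip(obs, pred)]
    assert report.total == pytest.approx(sum(singles))
    for (key, v), s in zip(sorted(report.per_omega.items()), singles):
        assert v == pytest.approx(s)


def test_extrinsic_loss_identical_pairs_zero(rng):
    times = np.linspace(0, 1, 4)
    ens = [_ens(times, rng.normal(size=(3, 4, 2)), omega=(float(k),))
           for k in range(2)]
    report = extrinsic_loss(_grid(ens), _grid(ens))
    assert report.total == 0.0


def test_extrinsic_loss_mismatched_omegas(rng):
    times = np.linspace(0, 1, 4)
    a = _ens(times, rng.normal(size=(3, 4, 1)), omega=(0.0,))
    b = _ens(times, rng.normal(size=(3, 4, 1)), omega=(1.0,))
    with pytest.raises(ValueError):
        extrinsic_loss(_grid([a]), _grid([b]))
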