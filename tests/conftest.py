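import numpy as np
import pytest

from endnsde.data import TrajectoryEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ensemble():
    """2 trajectories, 3 times, 2 state components, omega=(0.1, 0.2)."""
    times = np.array([0.0, 0.5, 1.0])
    values = np.array([
        [[0.0, 1.0], [0.1, 0.9], [0.2, 0.8]],
        [[0.0, 1.0], [-0.1, 1.1], [-0.2, 1.2]],
    ])
    return TrajectoryEnsemble(times=times, values=values,
                              omega=np.array([0.1, 0.2]),
                              state_labels=["x", "y"],
                              param_labels=["sigma0", "c"])


def make_ensemble(rng, n=4, T=5, d=2, omega=(0.3,)):
    times = np.sort(rng.uniform(0, 1, size=T))
    times[0] = 0.0
    return TrajectoryEnsemble(times=times, values=rng.normal(size=(n, T, d)),
                              omega=np.asarray(omega))
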