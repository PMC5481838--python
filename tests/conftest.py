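import numpy as np
import pytest

from subdiff.trackio import Trajectory, TrajectoryEnsemble


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170620)


def make_trajectory(xy, tid=0, dt=1.0, intensity=None, uncertainty=None):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(id=tid, frames=np.arange(len(xy)), xy=xy,
                      intensity=intensity, uncertainty=uncertainty,
                      frame_interval=dt)


def make_ensemble(paths, dt=1.0):
    trajs = [make_trajectory(p, tid=i, dt=dt) for i, p in enumerate(paths)]
    return TrajectoryEnsemble(trajs, frame_interval=dt)


@pytest.fixture
def gaussian_walk():
    """One long 2D Gaussian walk (unit per-coordinate step std)."""
    rng = np.random.default_rng(7)
    steps = rng.standard_normal((999, 2))
    return make_trajectory(np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)]))
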