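import numpy as np
import pytest

from hydroschool.model_core import SchoolState
from hydroschool.simulator import Trajectory
from hydroschool.model_core import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def triangular_patch(rows: int = 8, cols: int = 8, spacing: float = 1.0) -> np.ndarray:
    """Finite patch of a triangular lattice (every Delaunay edge = spacing)."""
    pts = []
    for r in range(rows):
        for c in range(cols):
            pts.append([c * spacing + (r % 2) * spacing / 2.0,
                        r * spacing * np.sqrt(3) / 2.0])
    return np.array(pts)


def rigid_trajectory(x0: np.ndarray, theta_of_t, times: np.ndarray,
                     seed: int = 0) -> Trajectory:
    """Trajectory of a rigid group whose common heading follows theta_of_t.

    All swimmers share the heading angle and move at unit speed; positions
    are trapezoid-integrated headings added to x0.
    """
    theta_t = np.asarray([theta_of_t(t) for t in times], dtype=float)
    n = x0.shape[0]
    theta = np.repeat(theta_t[:, None], n, axis=1)
    v = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    dt = times[1] - times[0]
    steps = 0.5 * (v[1:] + v[:-1]) * dt
    x = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)], axis=0)
    params = ModelParams(In=0.0, Ia=0.0, If=0.0, seed=seed)
    return Trajectory(params=params, times=times, x=x, theta=theta, v=v, stride=1)


@pytest.fixture
def polarized_state(rng):
    """Compact polarized school of 60 swimmers heading +x."""
    r = 4.0 * np.sqrt(rng.uniform(size=60))
    a = rng.uniform(-np.pi, np.pi, 60)
    x = np.column_stack([r * np.cos(a), r * np.sin(a)])
    return SchoolState(t=0.0, x=x, theta=np.zeros(60))
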