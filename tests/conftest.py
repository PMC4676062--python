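import numpy as np
import pytest

from ilmscan import AngleTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_angles(rng):
    """Small non-degenerate angle trajectory (10 frames, 7 sites)."""
    return AngleTrajectory(
        gamma=rng.uniform(-179.0, 179.0, (10, 7)),
        theta=rng.uniform(30.0, 150.0, (10, 7)),
    )


def make_angles(gamma, theta, **kw):
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return AngleTrajectory(gamma=gamma, theta=theta, **kw)
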