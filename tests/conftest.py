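import numpy as np
import pytest

from leadersim import ArenaConfig


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_poses(rng, config, n=4, min_sep=None):
    """Non-overlapping uniform random poses inside the allowed box."""
    r = config.robot_radius
    if min_sep is None:
        min_sep = config.robot_diameter
    while True:
        xy = rng.uniform(r, config.side_length - r, size=(n, 2))
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        if (d[np.triu_indices(n, 1)] >= min_sep).all():
            break
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([xy, th])
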