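import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk(n=3000, radius=150.0, seed=0):
    rng = np.random.default_rng(seed)
    u, th = rng.random(n), rng.random(n) * 2 * np.pi
    r = radius * np.sqrt(u)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def make_star(n_disk=3000, n_arm=400, radius=150.0, n_arms=5, seed=0):
    """A filled disk with ``n_arms`` radial arms reaching 2x the disk radius."""
    rng = np.random.default_rng(seed)
    disk = make_disk(n_disk, radius, seed)
    arms = []
    for k in range(n_arms):
        ang = 2 * np.pi * k / n_arms
        rr = radius + rng.random(n_arm) * radius
        w = (rng.random(n_arm) - 0.5) * 40.0
        ca, sa = np.cos(ang), np.sin(ang)
        arms.append(np.stack([rr * ca - w * sa, rr * sa + w * ca], axis=1))
    return np.vstack([disk] + arms)


@pytest.fixture
def star_positions():
    return make_star()


@pytest.fixture
def disk_positions():
    return make_disk()
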