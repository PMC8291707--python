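import math

import numpy as np
import pytest

from crvtoffset import load_calibration


@pytest.fixture(scope="session")
def calibration():
    return load_calibration()


def regular_polygon(n=48, radius=1.0, center=(0.0, 0.0)):
    theta = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack(
        (center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta))
    )


def random_convex_polygon(rng, n=48):
    """Random affine image of a regular n-gon: always strictly convex."""
    base = regular_polygon(n)
    a = rng.normal(size=(2, 2))
    spd = a @ a.T + 0.3 * np.eye(2)  # symmetric positive definite
    shift = rng.normal(scale=2.0, size=2)
    return base @ spd.T + shift


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
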