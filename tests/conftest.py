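import numpy as np
import pytest

from blebdyn.breathing import default_breathing
from blebdyn.core import (
    MaterialParameters,
    default_fluid,
    default_geometry,
    default_material,
    default_membrane,
    default_transmural_pressure,
)


@pytest.fixture(scope="session")
def mat():
    return default_material()


@pytest.fixture(scope="session")
def mat_unstable():
    """Material point reported to satisfy the determinant instability criterion."""
    return MaterialParameters(c1=-22.5e5, c2=1.26, c3=-1.39e6)


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def mem():
    return default_membrane()


@pytest.fixture(scope="session")
def fluid():
    return default_fluid()


@pytest.fixture(scope="session")
def P_mean():
    return default_transmural_pressure()


@pytest.fixture(scope="session")
def bm():
    return default_breathing()


def draw_physical_materials(rng: np.random.Generator, n: int) -> list[MaterialParameters]:
    """Random physical material parameters: c1, c3 log-uniform negative, c2 in (0, 3]."""
    c1 = -(10.0 ** rng.uniform(4.5, 7.5, n))
    c3 = -(10.0 ** rng.uniform(4.5, 7.5, n))
    c2 = rng.uniform(1e-3, 3.0, n)
    return [MaterialParameters(c1=a, c2=b, c3=c) for a, b, c in zip(c1, c2, c3)]
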