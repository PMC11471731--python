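"""Shared fixtures: geometries, small hand-built masks, phantom bundles."""

from __future__ import annotations

import numpy as np
import pytest

from jcwmh.phantom import PhantomSpec, generate
from jcwmh.rasters import BinaryMask, ProbabilityMap, VolumeGeometry

GEOM09 = VolumeGeometry(0.9, 0.9, 6.0)


@pytest.fixture
def geom() -> VolumeGeometry:
    return GEOM09


@pytest.fixture
def unit_geom() -> VolumeGeometry:
    return VolumeGeometry(1.0, 1.0)


def mask(pixels, geometry=GEOM09) -> BinaryMask:
    return BinaryMask(np.asarray(pixels, dtype=bool), geometry)


def blank(shape=(64, 64), geometry=GEOM09) -> np.ndarray:
    return np.zeros(shape, dtype=bool)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bundle():
    """One default 256-px phantom, shared read-only across tests."""
    return generate(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def bundle128():
    """One 128-px phantom (the surrogate-model working size)."""
    return generate(PhantomSpec(image_size=128, seed=21))
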