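"""Shared fixtures: a study-scale template pair and small helper grids.

The 64-cube grid at 3.44 mm spacing covers the same 220 mm field of
view as a 128-matrix scan at 1.72 mm; building templates once per
session keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from atrspect.imaging_core import BinaryVOI, Grid, Volume, centered_grid
from atrspect.phantom import make_template_pair

STUDY_SHAPE = (64, 64, 64)
STUDY_SPACING = 3.44


@pytest.fixture(scope="session")
def study_assets():
    """(TemplatePair, LabelVolume atlas, VOI dict) on the study grid."""
    return make_template_pair(STUDY_SHAPE, STUDY_SPACING, seed=0)


@pytest.fixture(scope="session")
def pair(study_assets):
    return study_assets[0]


@pytest.fixture(scope="session")
def atlas(study_assets):
    return study_assets[1]


@pytest.fixture(scope="session")
def vois(study_assets):
    return study_assets[2]


@pytest.fixture()
def small_grid() -> Grid:
    return centered_grid((16, 16, 16), 2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_volume(grid: Grid, rng, positive=True) -> Volume:
    data = rng.random(grid.shape)
    if positive:
        data = data + 0.1
    return Volume(data, grid)


def full_mask(grid: Grid) -> BinaryVOI:
    return BinaryVOI(np.ones(grid.shape, dtype=bool), grid)
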