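"""Shared fixtures: synthetic cells, meshes, and seeded RNGs.

All fixtures are generated programmatically so the suite carries no data
files; seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from slayer.profile import CellRecord
from slayer.synthetic import (CellGeometry, ImageSimConfig, LabelPattern,
                              make_spherocylinder_mesh, simulate_cell_image)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_cell():
    """Noise-on STED-like cell with a uniform outline label (no stalk)."""
    cfg = ImageSimConfig(
        channel_patterns=(LabelPattern("uniform", 3000),), rng_seed=2)
    return simulate_cell_image(cfg)


@pytest.fixture
def uniform_record(uniform_cell):
    """Fresh CellRecord for the shared uniform cell (tests may mutate it)."""
    return CellRecord(uniform_cell.transmitted.copy(),
                      uniform_cell.channels[0].copy(),
                      pixel_size=uniform_cell.pixel_size,
                      stalk_side="left")


@pytest.fixture(scope="session")
def spherocylinder():
    """2 um body, 400 nm radius capsule mesh (nm units)."""
    return make_spherocylinder_mesh(2000.0, 400.0, subdivisions=32)


@pytest.fixture(scope="session")
def stalked_cell():
    """Cell with a stalk on the left, for orientation/mirroring tests."""
    cfg = ImageSimConfig(
        channel_patterns=(LabelPattern("uniform", 2000),),
        cell_geometry=CellGeometry(stalk_length=800.0), rng_seed=4)
    return simulate_cell_image(cfg)
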