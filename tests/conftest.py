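"""Shared fixtures: small deterministic grids and simulator scenes."""

from __future__ import annotations

import numpy as np
import pytest

from ilee import SceneSpec, VoxelGeometry, VoxelGrid, generate_artificial_image, synth_scene


@pytest.fixture
def geom2d() -> VoxelGeometry:
    return VoxelGeometry(u_xy=0.132)


@pytest.fixture
def geom3d() -> VoxelGeometry:
    return VoxelGeometry(u_xy=0.132, u_z=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def grid2d(values, u_xy: float = 1.0, bit_depth: int = 12) -> VoxelGrid:
    return VoxelGrid(values=np.asarray(values, dtype=float), geometry=VoxelGeometry(u_xy=u_xy), bit_depth=bit_depth)


def grid3d(values, u_xy: float = 1.0, u_z: float = 1.0, bit_depth: int = 12) -> VoxelGrid:
    return VoxelGrid(
        values=np.asarray(values, dtype=float),
        geometry=VoxelGeometry(u_xy=u_xy, u_z=u_z),
        bit_depth=bit_depth,
    )


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 3D scene with a handful of tubes."""
    spec = SceneSpec(shape=(32, 128, 128), n_filaments=4, length_range=(50, 100), radius_range=(1.5, 3), seed=5)
    return synth_scene(spec)


@pytest.fixture(scope="session")
def small_artificial(small_scene):
    """(grid, truth mask, ground truth dict) for the small scene."""
    return generate_artificial_image(small_scene, seed=5)
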