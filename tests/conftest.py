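"""Shared fixtures: small grids, random cohorts, toy parcellations."""

from __future__ import annotations

import numpy as np
import pytest

from lesionmap.volumes import BinaryLesionMask, Parcellation, VoxelGrid


def make_grid(shape=(8, 8, 8), voxel_mm=2.0, origin=None) -> VoxelGrid:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    if origin is None:
        origin = [-voxel_mm * (s - 1) / 2.0 for s in shape]
    affine[:3, 3] = origin
    return VoxelGrid(shape=tuple(shape), affine=affine)


def random_mask(grid: VoxelGrid, rng: np.random.Generator,
                p: float = 0.3, subject_id: str = "sub") -> BinaryLesionMask:
    data = (rng.random(grid.shape) < p).astype(np.uint8)
    return BinaryLesionMask(grid=grid, data=data, subject_id=subject_id)


def random_cohort(grid: VoxelGrid, n: int, rng: np.random.Generator,
                  p: float = 0.3) -> list[BinaryLesionMask]:
    return [random_mask(grid, rng, p, f"sub_{i:02d}") for i in range(n)]


def random_parcellation(grid: VoxelGrid, k: int,
                        rng: np.random.Generator) -> Parcellation:
    labels = rng.integers(1, k + 1, size=grid.shape).astype(np.int32)
    lookup = {i: f"parcel_{i}" for i in range(1, k + 1)}
    return Parcellation(grid=grid, labels=labels, lookup=lookup)


@pytest.fixture
def grid8() -> VoxelGrid:
    return make_grid((8, 8, 8))


@pytest.fixture
def grid10() -> VoxelGrid:
    return make_grid((10, 10, 10))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
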