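"""Volumetric containers and I/O: voxel grids, binary lesion masks, parcellations.

All volumes live on a :class:`VoxelGrid` — a shape plus a 4x4 affine mapping
0-based voxel indices to world millimetre coordinates, following the NIfTI
convention (voxel centres at integer indices).  Cohort analyses require every
volume to sit on the same grid; resampling between grids is nearest-neighbour
only, so binary masks stay binary and parcel labels are never invented.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyCohortError, GridMismatchError

#: absolute tolerance on affine entries when deciding grid compatibility
AFFINE_ATOL = 1e-5


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice: array shape plus voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible(self, other: "VoxelGrid", atol: float = AFFINE_ATOL) -> bool:
        """True iff shapes match and affines agree within ``atol`` entrywise."""
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, rtol=0.0, atol=atol)
        )

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class BinaryLesionMask:
    """Per-subject binary lesion volume: 1 = lesioned voxel, 0 = spared."""

    grid: VoxelGrid
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask data must contain only 0 and 1")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def n_lesioned(self) -> int:
        return int(self.data.sum())

    @property
    def lesion_volume_mm3(self) -> float:
        return self.n_lesioned * float(np.prod(self.grid.voxel_size))


@dataclass(frozen=True)
class Parcellation:
    """Integer-labelled partition of the grid; 0 is background, not a parcel."""

    grid: VoxelGrid
    labels: np.ndarray
    lookup: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"label shape {labels.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if labels.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        present = set(int(v) for v in np.unique(labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels missing from lookup table: {sorted(missing)}")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def parcel_labels(self) -> list[int]:
        """Sorted nonzero labels declared in the lookup table."""
        return sorted(int(k) for k in self.lookup)


def _grid_from_img(img: nib.spatialimages.SpatialImage) -> VoxelGrid:
    return VoxelGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def load_mask(path: str | os.PathLike, binarize_threshold: float = 0.0,
              subject_id: str | None = None) -> BinaryLesionMask:
    """Load a NIfTI volume as a binary lesion mask.

    Voxels with value strictly greater than ``binarize_threshold`` become 1;
    the default (0) binarizes "any nonzero", absorbing interpolation residue
    that nominally-binary tracings sometimes carry.

    Parameters
    ----------
    path : path to a .nii or .nii.gz volume
    binarize_threshold : values > this become lesioned
    subject_id : defaults to the file stem
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if subject_id is None:
        subject_id = os.path.basename(str(path)).split(".")[0]
    binary = (data > binarize_threshold).astype(np.uint8)
    return BinaryLesionMask(grid=_grid_from_img(img), data=binary, subject_id=subject_id)


def save_mask(mask: BinaryLesionMask, path: str | os.PathLike) -> None:
    """Write a binary mask as a uint8 NIfTI volume."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def save_volume(data: np.ndarray, grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write an arbitrary array (counts, proportions, differences) as NIfTI."""
    if data.shape != grid.shape:
        raise ValueError("data shape does not match grid shape")
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    nib.save(img, str(path))


def load_parcellation(path: str | os.PathLike,
                      lut_path: str | os.PathLike | None = None) -> Parcellation:
    """Load an integer-labelled NIfTI parcellation, optionally with a TSV lookup.

    Without a lookup table, parcels are named ``parcel_<label>``.
    """
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got shape {labels.shape}")
    labels = np.rint(labels).astype(np.int32)
    if lut_path is not None:
        lookup = read_lookup_table(lut_path)
    else:
        lookup = {int(v): f"parcel_{int(v)}" for v in np.unique(labels) if v != 0}
    return Parcellation(grid=_grid_from_img(img), labels=labels, lookup=lookup)


def save_parcellation(parc: Parcellation, path: str | os.PathLike,
                      lut_path: str | os.PathLike | None = None) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.grid.affine)
    nib.save(img, str(path))
    if lut_path is not None:
        write_lookup_table(parc.lookup, lut_path)


def read_lookup_table(path: str | os.PathLike) -> dict[int, str]:
    """Read a two-column TSV (integer label, region name); header row optional."""
    lookup: dict[int, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"lookup table line has fewer than 2 columns: {line!r}")
            try:
                label = int(cols[0])
            except ValueError:
                continue  # header row
            lookup[label] = cols[1]
    return lookup


def write_lookup_table(lookup: dict[int, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tregion_name\n")
        for label in sorted(lookup):
            fh.write(f"{label}\t{lookup[label]}\n")


def check_cohort_grids(masks: list[BinaryLesionMask]) -> VoxelGrid:
    """Return the shared grid of a cohort, or raise naming the offender."""
    if not masks:
        raise EmptyCohortError("cohort contains no masks")
    ref = masks[0]
    for m in masks[1:]:
        if not ref.grid.compatible(m.grid):
            raise GridMismatchError(
                f"subject {m.subject_id!r} is on a different grid than "
                f"subject {ref.subject_id!r}: shapes {m.grid.shape} vs {ref.grid.shape}"
            )
    return ref.grid


def _resample_array(source: np.ndarray, source_grid: VoxelGrid,
                    target: VoxelGrid) -> np.ndarray:
    """World-space nearest-neighbour resampling; outside the source FOV -> 0.

    Each target voxel centre is mapped to world mm and then into source voxel
    coordinates; the value of the nearest source voxel centre is taken.
    """
    # composed target-index -> source-index affine
    comp = np.linalg.inv(source_grid.affine) @ target.affine
    ii, jj, kk = np.meshgrid(*(np.arange(s, dtype=float) for s in target.shape),
                             indexing="ij")
    coords = np.stack([
        comp[0, 0] * ii + comp[0, 1] * jj + comp[0, 2] * kk + comp[0, 3],
        comp[1, 0] * ii + comp[1, 1] * jj + comp[1, 2] * kk + comp[1, 3],
        comp[2, 0] * ii + comp[2, 1] * jj + comp[2, 2] * kk + comp[2, 3],
    ])
    return ndimage.map_coordinates(source, coords, order=0,
                                   mode="grid-constant", cval=0)


def resample_nearest(source: BinaryLesionMask | Parcellation,
                     target: VoxelGrid) -> BinaryLesionMask | Parcellation:
    """Resample a mask or parcellation onto ``target`` by nearest neighbour.

    Identity grids short-circuit to an exact copy, so identity resampling is
    a strict no-op.
    """
    if isinstance(source, BinaryLesionMask):
        if source.grid.compatible(target):
            return replace(source, grid=target)
        out = _resample_array(source.data, source.grid, target)
        return BinaryLesionMask(grid=target, data=out.astype(np.uint8),
                                subject_id=source.subject_id)
    if isinstance(source, Parcellation):
        if source.grid.compatible(target):
            return replace(source, grid=target)
        out = _resample_array(source.labels, source.grid, target)
        return Parcellation(grid=target, labels=out.astype(np.int32),
                            lookup=dict(source.lookup))
    raise TypeError(f"cannot resample object of type {type(source).__name__}")


def load_cohort(directory: str | os.PathLike,
                binarize_threshold: float = 0.0) -> list[BinaryLesionMask]:
    """Load every .nii/.nii.gz in a directory as a cohort, sorted by filename."""
    names = sorted(
        f for f in os.listdir(directory)
        if f.endswith(".nii") or f.endswith(".nii.gz")
    )
    if not names:
        raise EmptyCohortError(f"no NIfTI files found in {directory}")
    return [load_mask(os.path.join(directory, n), binarize_threshold) for n in names]
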