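"""Cohort lesion overlays: voxelwise counts, proportion maps, threshold maps.

The overlay of a cohort counts, at each voxel, how many subjects have a lesion
there.  Dividing by cohort size gives the proportion map; thresholding the
proportion map at a fraction tau (e.g. 0.80) extracts the voxels lesioned in
at least that fraction of the cohort — the cohort's "common lesion".

Proportions are computed in exact-count space: integer counts are summed
first and divided once, so every value is an exact multiple of 1/n and the
threshold comparison operates on exact rationals rather than accumulated
floats (with n = 39 the boundary matters: 32/39 ~ 0.8205 passes a 0.80
threshold, 31/39 ~ 0.7949 does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyCohortError, ParameterError
from .volumes import BinaryLesionMask, VoxelGrid, check_cohort_grids


@dataclass(frozen=True)
class CountOverlay:
    """Voxelwise count of subjects lesioned at each voxel."""

    grid: VoxelGrid
    counts: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid shape")
        if counts.min() < 0 or counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")
        object.__setattr__(self, "counts", counts.astype(np.int64))


@dataclass(frozen=True)
class ProportionMap:
    """Voxelwise fraction of a cohort lesioned at each voxel, in [0, 1]."""

    grid: VoxelGrid
    values: np.ndarray
    n_subjects: int
    cohort_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid shape")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def max_proportion(self) -> float:
        """Global maximum — the cohort's peak lesion overlap."""
        return float(self.values.max())


def count_overlay(masks: list[BinaryLesionMask]) -> CountOverlay:
    """Overlap a cohort's lesions: voxelwise sum of the binary masks."""
    if not masks:
        raise EmptyCohortError("cannot build an overlay from an empty cohort")
    grid = check_cohort_grids(masks)
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        counts += m.data
    return CountOverlay(grid=grid, counts=counts, n_subjects=len(masks))


def proportion_map(masks: list[BinaryLesionMask], cohort_name: str = "") -> ProportionMap:
    """Cohort proportion map: overlay counts divided by the number of subjects."""
    ov = count_overlay(masks)
    return ProportionMap(grid=ov.grid, values=ov.counts / ov.n_subjects,
                         n_subjects=ov.n_subjects, cohort_name=cohort_name)


def threshold_map(pm: ProportionMap, tau: float) -> BinaryLesionMask:
    """Voxels lesioned in at least a fraction ``tau`` of the cohort.

    The comparison is inclusive (>= tau): a voxel at exactly the threshold
    survives.  ``threshold_map(pm, 0.80)`` on the patient cohort yields the
    cohort's common lesion.
    """
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"threshold tau must lie in [0, 1], got {tau}")
    data = (pm.values >= tau).astype(np.uint8)
    if tau == 0.0:
        # every voxel satisfies >= 0; restrict to voxels with any lesion
        data = (pm.values > 0.0).astype(np.uint8)
    name = f"{pm.cohort_name or 'cohort'}_common_lesion_tau{tau:g}"
    return BinaryLesionMask(grid=pm.grid, data=data, subject_id=name)
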