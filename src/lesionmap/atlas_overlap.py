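"""Parcel-wise overlap between a binary map and a labelled atlas.

For each atlas parcel the table reports what percent of that parcel's voxels
fall inside the binary map (parcel-normalized: 100 x overlapped / parcel
size).  This is the direction in which a small region engulfed by a large
lesion reads near 100%, which is how near-ceiling insular overlaps arise in
practice.  Every nonzero label in the lookup table gets a row, including 0%
rows, so tables from different maps are always alignable.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import EmptyAtlasError, GridMismatchError
from .volumes import BinaryLesionMask, Parcellation, resample_nearest

#: column order of a parcel-overlap table
OVERLAP_COLUMNS = ["label", "region_name", "parcel_voxels",
                   "overlapped_voxels", "percent_overlap"]


def parcel_overlap(map_: BinaryLesionMask, parc: Parcellation,
                   resample: bool = True) -> pd.DataFrame:
    """Percent of each parcel's voxels covered by the binary map.

    If the map and parcellation grids differ and ``resample`` is true, the map
    is first resampled onto the parcellation's grid by nearest neighbour (the
    percentages are therefore computed on the atlas grid).  Rows are sorted by
    descending percent_overlap, ties broken by ascending label.

    Returns a DataFrame with columns label, region_name, parcel_voxels,
    overlapped_voxels, percent_overlap.
    """
    labels_declared = parc.parcel_labels
    if not labels_declared:
        raise EmptyAtlasError("parcellation declares no nonzero labels")
    if not map_.grid.compatible(parc.grid):
        if not resample:
            raise GridMismatchError("map and parcellation are on incompatible grids")
        map_ = resample_nearest(map_, parc.grid)
        if not map_.grid.compatible(parc.grid):  # pragma: no cover - defensive
            raise GridMismatchError("resampling failed to align map with parcellation")

    labels = parc.labels
    max_label = max(int(labels.max()), max(labels_declared))
    parcel_voxels = np.bincount(labels.ravel(), minlength=max_label + 1)
    overlapped = np.bincount(labels.ravel(), weights=map_.data.ravel().astype(float),
                             minlength=max_label + 1).astype(np.int64)

    rows = []
    for label in labels_declared:
        pv = int(parcel_voxels[label])
        ov = int(overlapped[label])
        pct = 100.0 * ov / pv if pv > 0 else 0.0
        rows.append((label, parc.lookup[label], pv, ov, pct))
    table = pd.DataFrame(rows, columns=OVERLAP_COLUMNS)
    table = table.sort_values(["percent_overlap", "label"],
                              ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)


def write_overlap_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a parcel-overlap table as CSV.

    ``percent_overlap`` keeps full machine precision; a companion
    ``percent_overlap_display`` column carries the one-decimal rendering.
    """
    out = table.copy()
    out["percent_overlap_display"] = out["percent_overlap"].map(lambda v: f"{v:.1f}")
    out.to_csv(path, index=False)


def read_overlap_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_overlap_table`."""
    table = pd.read_csv(path)
    return table[OVERLAP_COLUMNS]
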