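"""Indirect structural disconnection: lesion mask vs normative streamline atlas.

Instead of patient diffusion imaging, white-matter damage is estimated by
embedding the lesion in a normative tractography atlas: a tract's
disconnection index is the percent of its streamlines that pass through the
lesion.  A streamline counts as disconnected on any lesion contact; contact
is decided by walking the polyline at sub-voxel steps (half the smallest
voxel edge), so a streamline cannot step over a one-voxel-thick lesion
between two distant vertices.

Tract atlases are read from TRK/TCK streamline files (one file per named
bundle, via nibabel) or from a plain JSON dialect::

    {"name": "arcuate_fasciculus", "streamlines": [[[x, y, z], ...], ...]}

with coordinates in world mm.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyBundleError, ParameterError
from .volumes import BinaryLesionMask

#: column order of a disconnection table
DISCONNECTION_COLUMNS = ["tract_name", "total_streamlines",
                         "disconnected_streamlines", "disconnection_index"]


@dataclass(frozen=True)
class TractBundle:
    """A named white-matter tract: a list of (N_i, 3) world-mm polylines."""

    name: str
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise EmptyBundleError(f"bundle {self.name!r} has no streamlines")
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ParameterError(
                    f"bundle {self.name!r}, streamline {i}: need an (N>=2, 3) array"
                )
            if not np.isfinite(arr).all():
                raise ParameterError(
                    f"bundle {self.name!r}, streamline {i}: non-finite coordinates"
                )
            cleaned.append(arr)
        object.__setattr__(self, "streamlines", cleaned)

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


def _densify(points: np.ndarray, max_step: float) -> np.ndarray:
    """Insert points so no segment of the polyline exceeds ``max_step`` mm."""
    segs = np.diff(points, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    if (lengths <= max_step).all():
        return points
    pieces = [points[:1]]
    for start, seg, length in zip(points[:-1], segs, lengths):
        n = max(1, int(np.ceil(length / max_step)))
        t = np.arange(1, n + 1)[:, None] / n
        pieces.append(start[None, :] + t * seg[None, :])
    return np.vstack(pieces)


def streamline_hits_mask(streamline: np.ndarray, mask: BinaryLesionMask) -> bool:
    """True iff any sampled point of the streamline lies in a lesioned voxel.

    Points are mapped world -> voxel through the inverse affine and assigned
    to the nearest voxel index (voxel centres at integer indices); segments
    are subdivided to half the minimum voxel edge first.
    """
    if not mask.data.any():
        return False
    points = np.asarray(streamline, dtype=float)
    step = 0.5 * min(mask.grid.voxel_size)
    points = _densify(points, step)
    vox = np.rint(mask.grid.world_to_voxel(points)).astype(np.int64)
    shape = mask.grid.shape
    inside = ((vox >= 0) & (vox < np.array(shape))).all(axis=1)
    if not inside.any():
        return False
    vox = vox[inside]
    return bool(mask.data[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def tract_disconnection(bundle: TractBundle, mask: BinaryLesionMask) -> dict:
    """One disconnection-table row for a bundle.

    disconnection_index = 100 x (streamlines hitting the lesion) / total.
    """
    if bundle.n_streamlines == 0:  # unreachable via TractBundle, kept for raw input
        raise EmptyBundleError(f"bundle {bundle.name!r} is empty")
    hits = sum(streamline_hits_mask(s, mask) for s in bundle.streamlines)
    return {
        "tract_name": bundle.name,
        "total_streamlines": bundle.n_streamlines,
        "disconnected_streamlines": int(hits),
        "disconnection_index": 100.0 * hits / bundle.n_streamlines,
    }


def disconnection_report(atlas: list[TractBundle],
                         mask: BinaryLesionMask) -> pd.DataFrame:
    """Per-tract disconnection indices, sorted by descending index then name."""
    if not atlas:
        raise EmptyBundleError("tract atlas contains no bundles")
    rows = [tract_disconnection(b, mask) for b in atlas]
    table = pd.DataFrame(rows, columns=DISCONNECTION_COLUMNS)
    table = table.sort_values(["disconnection_index", "tract_name"],
                              ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)


def write_disconnection_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table.copy()
    out["disconnection_index_display"] = out["disconnection_index"].map(
        lambda v: f"{v:.1f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# atlas I/O

def load_bundle(path: str | os.PathLike, name: str | None = None) -> TractBundle:
    """Load one bundle from a .trk, .tck, or .json streamline file."""
    path = str(path)
    base = os.path.basename(path)
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        bundle_name = name or payload.get("name") or base[: -len(".json")]
        streamlines = [np.asarray(s, dtype=float) for s in payload["streamlines"]]
        return TractBundle(name=bundle_name, streamlines=streamlines)
    if path.endswith(".trk") or path.endswith(".tck"):
        tract = nib.streamlines.load(path)  # yields world-mm (RAS) points
        stem = base.rsplit(".", 1)[0]
        return TractBundle(name=name or stem,
                           streamlines=[np.asarray(s) for s in tract.streamlines])
    raise ValueError(f"unsupported streamline file: {path}")


def save_bundle_json(bundle: TractBundle, path: str | os.PathLike) -> None:
    payload = {"name": bundle.name,
               "streamlines": [s.tolist() for s in bundle.streamlines]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def save_bundle_tck(bundle: TractBundle, path: str | os.PathLike) -> None:
    tractogram = nib.streamlines.Tractogram(bundle.streamlines,
                                            affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def load_tract_atlas(directory: str | os.PathLike) -> list[TractBundle]:
    """Load every bundle file in a directory, sorted by filename."""
    names = sorted(
        f for f in os.listdir(directory)
        if f.endswith((".trk", ".tck", ".json"))
    )
    if not names:
        raise EmptyBundleError(f"no streamline files found in {directory}")
    return [load_bundle(os.path.join(directory, n)) for n in names]
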