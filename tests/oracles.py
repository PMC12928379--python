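"""Independent brute-force oracles used by the test suite.

Everything here is written as plain Python loops over voxels or closed-form
geometry, deliberately sharing no code path with the library: these are the
reference answers the vectorised implementation is checked against.
"""

from __future__ import annotations

import numpy as np


def count_overlay_loop(mask_arrays: list[np.ndarray]) -> np.ndarray:
    """Per-voxel subject tally by explicit triple loop."""
    shape = mask_arrays[0].shape
    counts = np.zeros(shape, dtype=int)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                c = 0
                for m in mask_arrays:
                    if m[i, j, k]:
                        c += 1
                counts[i, j, k] = c
    return counts


def threshold_loop(values: np.ndarray, tau: float) -> np.ndarray:
    """Proportion-map thresholding: 1 iff value >= tau and the voxel is
    lesioned in at least one subject (so tau=0 keeps any-lesion voxels)."""
    out = np.zeros(values.shape, dtype=int)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                v = values[i, j, k]
                out[i, j, k] = 1 if (v >= tau and v > 0) else 0
    return out


def binarize_loop(values: np.ndarray, tau: float) -> np.ndarray:
    """Plain inclusive >= tau binarization (subtraction-map rule)."""
    out = np.zeros(values.shape, dtype=int)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                out[i, j, k] = 1 if values[i, j, k] >= tau else 0
    return out


def subtract_loop(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros(a.shape, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                out[i, j, k] = a[i, j, k] - b[i, j, k]
    return out


def parcel_overlap_loop(map_array: np.ndarray, labels: np.ndarray) -> dict[int, tuple[int, int]]:
    """{label: (parcel_voxels, overlapped_voxels)} by voxel-by-voxel tally."""
    tally: dict[int, list[int]] = {}
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            for k in range(labels.shape[2]):
                lab = int(labels[i, j, k])
                if lab == 0:
                    continue
                entry = tally.setdefault(lab, [0, 0])
                entry[0] += 1
                if map_array[i, j, k]:
                    entry[1] += 1
    return {lab: (pv, ov) for lab, (pv, ov) in tally.items()}


def segment_crosses_slab(p0: np.ndarray, p1: np.ndarray, axis: int,
                         slab_lo: float, slab_hi: float) -> bool:
    """Closed-form: does the world-space segment p0-p1 enter [slab_lo, slab_hi]
    on the given axis?  (Axis-aligned slab of infinite extent otherwise.)"""
    a, b = float(p0[axis]), float(p1[axis])
    lo, hi = min(a, b), max(a, b)
    return not (hi < slab_lo or lo > slab_hi)


def streamline_hits_mask_walk(points: np.ndarray, mask: np.ndarray,
                              affine: np.ndarray, n_steps: int = 2000) -> bool:
    """Dense uniform walk along the polyline, nearest-voxel lookup per step.

    Uses a fixed, very fine step count per segment rather than the library's
    voxel-size-derived subdivision, so the two routes are independent.
    """
    inv = np.linalg.inv(affine)
    for p0, p1 in zip(points[:-1], points[1:]):
        for t in np.linspace(0.0, 1.0, n_steps):
            w = (1 - t) * np.asarray(p0, float) + t * np.asarray(p1, float)
            v = inv[:3, :3] @ w + inv[:3, 3]
            idx = np.rint(v).astype(int)
            if ((idx >= 0).all() and (idx < np.array(mask.shape)).all()
                    and mask[idx[0], idx[1], idx[2]]):
                return True
    return False
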