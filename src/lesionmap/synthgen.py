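"""Seeded synthetic data: lesion cohorts, parcellations, tract atlases.

The generators emulate the contrast studied in chronic-aphasia lesion mapping:
a patient-like cohort with large, heavily overlapping lesions around a core
territory, and a recovered-control cohort ("within normal limits") with
smaller, scattered lesions.  Lesions are geometric — a jittered sphere per
subject, optionally unioned with a fixed core region — because the analysis
pipeline only ever consumes binary masks, and geometric ground truth makes
every downstream number independently checkable.

All random draws are truncated at three standard deviations.  That gives each
cohort a hard spatial envelope (centre jitter and radius cannot exceed
mean + 3 sd), so statements like "no lesion of cohort A can reach this
corridor" are guaranteed by construction for every seed, not just typical
ones.

Randomness protocol (relied on by parameter-recovery tests): for a cohort of
n subjects a single ``numpy.random.default_rng(seed)`` stream is consumed in
this fixed order:

1. ``rng.random(n)`` compared against ``core_hit_rate`` (core inclusion),
2. ``rng.normal(0, jitter_sd, (n, 3))`` centre offsets (truncated at 3 sd),
3. ``rng.normal(radius_mean, radius_sd, n)`` radii (truncated at 3 sd and
   floored at ``MIN_LESION_RADIUS_MM``).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .volumes import BinaryLesionMask, Parcellation, VoxelGrid

#: lesions smaller than this radius (mm) are not anatomically meaningful
MIN_LESION_RADIUS_MM = 2.0


def default_grid(n: int = 64, voxel_mm: float = 2.0) -> VoxelGrid:
    """The desk-scale synthetic grid: n^3 voxels, isotropic, world-centred."""
    offset = -voxel_mm * (n - 1) / 2.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = offset
    return VoxelGrid(shape=(n, n, n), affine=affine)


def _voxel_centers_mm(grid: VoxelGrid) -> np.ndarray:
    """(X, Y, Z, 3) array of voxel-centre world coordinates."""
    idx = np.stack(np.meshgrid(*(np.arange(s, dtype=float) for s in grid.shape),
                               indexing="ij"), axis=-1)
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def _world_bounds(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounds (lo, hi) of the voxel-centre lattice in mm."""
    corners = np.array([[i, j, k] for i in (0, grid.shape[0] - 1)
                        for j in (0, grid.shape[1] - 1)
                        for k in (0, grid.shape[2] - 1)], dtype=float)
    world = grid.voxel_to_world(corners)
    return world.min(axis=0), world.max(axis=0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic lesion cohort.

    ``core_hit_rate`` is the probability that a subject's lesion is unioned
    with the fixed core sphere; 1.0 plants the core in every subject, 0.0 in
    none.  Per-subject lesion spheres have centre = core centre + truncated
    Gaussian jitter and radius drawn from a truncated Gaussian.
    """

    n_subjects: int
    core_center_mm: tuple[float, float, float]
    core_radius_mm: float
    core_hit_rate: float
    lesion_radius_mean: float
    lesion_radius_sd: float
    jitter_sd: float
    seed: int
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not 0.0 <= self.core_hit_rate <= 1.0:
            raise ParameterError("core_hit_rate must lie in [0, 1]")
        if self.core_radius_mm <= 0 or self.lesion_radius_mean <= 0:
            raise ParameterError("radii must be positive")
        if self.lesion_radius_sd < 0 or self.jitter_sd < 0:
            raise ParameterError("standard deviations must be non-negative")

    @property
    def max_reach_mm(self) -> float:
        """Hard upper bound on the distance a lesion voxel can lie from the
        core centre (centre jitter + radius, both truncated at 3 sd)."""
        return (3.0 * self.jitter_sd
                + self.lesion_radius_mean + 3.0 * self.lesion_radius_sd)


@dataclass(frozen=True)
class GroundTruth:
    """Everything a recovery test needs: bit-reproducible from (spec, seed)."""

    spec: CohortSpec
    core_voxel_indices: np.ndarray          # (M, 3) voxel indices of the core
    core_included: np.ndarray               # (n,) bool, the Bernoulli draws
    centers_mm: np.ndarray                  # (n, 3) lesion centres
    radii_mm: np.ndarray                    # (n,) lesion radii
    expected_core_proportion: float         # = core_hit_rate
    empirical_core_fraction: float = field(default=0.0)

    def to_jsonable(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "core_voxel_indices": self.core_voxel_indices.tolist(),
            "core_included": self.core_included.astype(int).tolist(),
            "centers_mm": self.centers_mm.tolist(),
            "radii_mm": self.radii_mm.tolist(),
            "expected_core_proportion": self.expected_core_proportion,
            "empirical_core_fraction": self.empirical_core_fraction,
        }


def _truncate(draws: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(draws, mean)
    return np.clip(draws, mean - 3.0 * sd, mean + 3.0 * sd)


def make_cohort(spec: CohortSpec, grid: VoxelGrid) -> tuple[list[BinaryLesionMask], GroundTruth]:
    """Generate a seeded cohort of spherical lesions around a core territory.

    Returns the per-subject binary masks and the machine-readable ground
    truth.  Identical (spec, grid) inputs give bit-identical outputs.
    """
    lo, hi = _world_bounds(grid)
    center = np.asarray(spec.core_center_mm, dtype=float)
    if ((center - spec.core_radius_mm) < lo).any() or ((center + spec.core_radius_mm) > hi).any():
        raise ParameterError(
            f"core sphere (centre {tuple(center)}, radius {spec.core_radius_mm} mm) "
            f"extends outside the grid world bounds {lo} .. {hi}"
        )

    rng = np.random.default_rng(spec.seed)
    core_included = rng.random(spec.n_subjects) < spec.core_hit_rate
    offsets = _truncate(rng.normal(0.0, spec.jitter_sd, (spec.n_subjects, 3)),
                        0.0, spec.jitter_sd)
    radii = _truncate(rng.normal(spec.lesion_radius_mean, spec.lesion_radius_sd,
                                 spec.n_subjects),
                      spec.lesion_radius_mean, spec.lesion_radius_sd)
    radii = np.maximum(radii, MIN_LESION_RADIUS_MM)
    centers = center[None, :] + offsets

    world = _voxel_centers_mm(grid)
    core_dist2 = ((world - center) ** 2).sum(axis=-1)
    core_mask = core_dist2 <= spec.core_radius_mm ** 2
    core_idx = np.argwhere(core_mask)

    masks: list[BinaryLesionMask] = []
    covered = 0
    for i in range(spec.n_subjects):
        dist2 = ((world - centers[i]) ** 2).sum(axis=-1)
        data = dist2 <= radii[i] ** 2
        if core_included[i]:
            data = data | core_mask
        if core_mask.any() and data[core_mask].all():
            covered += 1
        masks.append(BinaryLesionMask(
            grid=grid, data=data.astype(np.uint8),
            subject_id=f"{spec.name}_{i:03d}"))

    truth = GroundTruth(
        spec=spec,
        core_voxel_indices=core_idx,
        core_included=core_included,
        centers_mm=centers,
        radii_mm=radii,
        expected_core_proportion=spec.core_hit_rate,
        empirical_core_fraction=covered / spec.n_subjects,
    )
    return masks, truth


def make_parcellation(grid: VoxelGrid, k: int, seed: int,
                      sites_mm: np.ndarray | None = None) -> Parcellation:
    """Voronoi parcellation of the grid around k sites (labels 1..k).

    Sites default to k distinct voxel centres drawn uniformly at random;
    explicit world-mm sites may be supplied instead (k is then ignored).
    Every voxel is assigned the label of its nearest site, so the parcels
    partition the grid with no background.
    """
    world = _voxel_centers_mm(grid).reshape(-1, 3)
    if sites_mm is None:
        if not 1 <= k <= grid.n_voxels:
            raise ParameterError(f"k must lie in [1, {grid.n_voxels}], got {k}")
        rng = np.random.default_rng(seed)
        chosen = rng.choice(grid.n_voxels, size=k, replace=False)
        sites = world[chosen]
    else:
        sites = np.atleast_2d(np.asarray(sites_mm, dtype=float))
        k = len(sites)
        if k < 1:
            raise ParameterError("need at least one parcel site")
    _, nearest = cKDTree(sites).query(world, k=1)
    labels = (nearest + 1).astype(np.int32).reshape(grid.shape)
    lookup = {i + 1: f"parcel_{i + 1}" for i in range(k)}
    return Parcellation(grid=grid, labels=labels, lookup=lookup)


@dataclass(frozen=True)
class BundleSpec:
    """Recipe for one synthetic tract bundle.

    The corridor is a polyline in world mm; each streamline is the corridor
    shifted by a constant Gaussian offset (truncated at 3 sd), so straight
    corridors give straight streamlines and the bundle stays within
    corridor +/- 3*spread.
    """

    name: str
    corridor_mm: tuple[tuple[float, float, float], ...]
    n_streamlines: int
    spread_mm: float

    def __post_init__(self) -> None:
        if self.n_streamlines < 1:
            raise ParameterError("n_streamlines must be >= 1")
        if self.spread_mm < 0:
            raise ParameterError("spread_mm must be non-negative")
        if len(self.corridor_mm) < 2:
            raise ParameterError("corridor needs at least 2 points")


def make_tract_atlas(grid: VoxelGrid, bundle_specs: list[BundleSpec], seed: int):
    """Generate seeded tract bundles threading their corridors.

    Imported lazily typed: returns ``list[TractBundle]``.  Corridors (with
    their 3-sd spread envelope) must stay within the grid's world bounds.
    """
    from .disconnection import TractBundle

    lo, hi = _world_bounds(grid)
    rng = np.random.default_rng(seed)
    atlas = []
    for bs in bundle_specs:
        corridor = np.asarray(bs.corridor_mm, dtype=float)
        margin = 3.0 * bs.spread_mm
        if ((corridor - margin) < lo).any() or ((corridor + margin) > hi).any():
            raise ParameterError(
                f"bundle {bs.name!r}: corridor envelope leaves grid bounds")
        offsets = _truncate(rng.normal(0.0, bs.spread_mm, (bs.n_streamlines, 3)),
                            0.0, bs.spread_mm)
        streamlines = [corridor + off[None, :] for off in offsets]
        atlas.append(TractBundle(name=bs.name, streamlines=streamlines))
    return atlas


# ---------------------------------------------------------------------------
# the default two-cohort study scenario

#: core territory planted in every patient-like subject
CORE_CENTER_MM = (-24.0, -10.0, 0.0)
CORE_RADIUS_MM = 18.0


def default_scenario_specs(seed: int, n_patients: int = 39, n_controls: int = 41
                           ) -> tuple[CohortSpec, CohortSpec]:
    """Cohort specs for the default contrast.

    The patient-like cohort has large lesions (radius 37.5 +/- 4 mm, roughly
    220 cc, tight 4 mm centre jitter) that always include the core; the
    control-like cohort has smaller scattered lesions (radius 24 +/- 6 mm,
    roughly 60 cc, 14 mm jitter) that never do.  Sub-seeds are derived so the
    two cohorts consume independent streams.
    """
    a = CohortSpec(
        n_subjects=n_patients, core_center_mm=CORE_CENTER_MM,
        core_radius_mm=CORE_RADIUS_MM, core_hit_rate=1.0,
        lesion_radius_mean=37.5, lesion_radius_sd=4.0, jitter_sd=4.0,
        seed=(seed * 2 + 1) % (2**31), name="broca_like")
    b = CohortSpec(
        n_subjects=n_controls, core_center_mm=CORE_CENTER_MM,
        core_radius_mm=CORE_RADIUS_MM, core_hit_rate=0.0,
        lesion_radius_mean=24.0, lesion_radius_sd=6.0, jitter_sd=14.0,
        seed=(seed * 2 + 2) % (2**31), name="wnl_like")
    return a, b


def default_parcellation(grid: VoxelGrid, seed: int,
                         spacing_vox: int = 8) -> Parcellation:
    """Voronoi parcellation around a jittered voxel lattice of sites.

    One site is pinned to the core centre so the core territory always owns a
    compact parcel; the remaining sites sit on a regular lattice with 1.5 mm
    jitter, giving convex-ish parcels about ``spacing_vox`` voxels across.
    """
    rng = np.random.default_rng(seed)
    half = spacing_vox // 2
    axes = [np.arange(half, s, spacing_vox, dtype=float) for s in grid.shape]
    lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    sites = grid.voxel_to_world(lattice)
    sites = sites + _truncate(rng.normal(0.0, 1.5, sites.shape), 0.0, 1.5)
    core = np.asarray(CORE_CENTER_MM)
    nearest = np.argmin(((sites - core) ** 2).sum(axis=1))
    sites[nearest] = core
    return make_parcellation(grid, k=len(sites), seed=seed, sites_mm=sites)


def default_bundle_specs() -> list[BundleSpec]:
    """Two probe bundles: one threading the core, one avoiding every lesion.

    The avoiding corridor sits in the opposite corner of the grid, farther
    from the core centre than any cohort's hard lesion reach, so its
    disconnection index is 0 by construction for every seed.
    """
    cx, cy, cz = CORE_CENTER_MM
    return [
        BundleSpec(name="core_crossing",
                   corridor_mm=((-55.0, cy, cz), (cx, cy, cz), (55.0, cy, cz)),
                   n_streamlines=50, spread_mm=2.0),
        BundleSpec(name="far_corner",
                   corridor_mm=((-55.0, 52.0, 52.0), (55.0, 52.0, 52.0)),
                   n_streamlines=50, spread_mm=1.0),
    ]


def write_dataset(out_dir: str | os.PathLike, seed: int,
                  grid: VoxelGrid | None = None,
                  n_patients: int = 39, n_controls: int = 41) -> dict:
    """Emit a ready-to-run dataset directory and return its manifest.

    Layout: ``cohort_a/``, ``cohort_b/`` (one .nii.gz mask per subject),
    ``atlas.nii.gz`` + ``atlas.tsv``, ``tracts/`` (JSON bundles) and
    ``truth.json`` with the full ground truth.
    """
    from .disconnection import save_bundle_json
    from .volumes import save_mask, save_parcellation

    grid = grid or default_grid()
    out_dir = str(out_dir)
    spec_a, spec_b = default_scenario_specs(seed, n_patients, n_controls)
    parc = default_parcellation(grid, seed=(seed * 2 + 3) % (2**31))
    atlas = make_tract_atlas(grid, default_bundle_specs(),
                             seed=(seed * 2 + 4) % (2**31))

    truths = {}
    for sub, spec in (("cohort_a", spec_a), ("cohort_b", spec_b)):
        cohort_dir = os.path.join(out_dir, sub)
        os.makedirs(cohort_dir, exist_ok=True)
        masks, truth = make_cohort(spec, grid)
        for m in masks:
            save_mask(m, os.path.join(cohort_dir, f"{m.subject_id}.nii.gz"))
        truths[sub] = truth.to_jsonable()

    save_parcellation(parc, os.path.join(out_dir, "atlas.nii.gz"),
                      os.path.join(out_dir, "atlas.tsv"))
    tract_dir = os.path.join(out_dir, "tracts")
    os.makedirs(tract_dir, exist_ok=True)
    for bundle in atlas:
        save_bundle_json(bundle, os.path.join(tract_dir, f"{bundle.name}.json"))

    core_site_label = int(parc.labels[tuple(
        np.rint(grid.world_to_voxel(np.asarray(CORE_CENTER_MM))[0]).astype(int))])
    manifest = {
        "seed": seed,
        "grid": {"shape": list(grid.shape), "affine": grid.affine.tolist()},
        "cohorts": truths,
        "core_parcel_label": core_site_label,
        "bundles": [bs.name for bs in default_bundle_specs()],
    }
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
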