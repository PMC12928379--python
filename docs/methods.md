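# Methods

This note documents the models, conventions and design choices behind
`lesionmap`, in the order the pipeline applies them.

## Grids and volumes

All volumes live on a `VoxelGrid`: an array shape plus a 4×4 affine mapping
0-based voxel indices to world millimetres, with voxel centres at integer
indices (the NIfTI convention; array axis order follows the file's stored
order and the affine carries anatomical orientation). Two grids are treated
as identical when their shapes match and their affines agree entrywise
within 1e-5 — loose enough to absorb float serialization noise across
save/load cycles, far too tight to mask a real registration mismatch.

Lesion masks are nominally binary but traced files sometimes carry
interpolation residue, so loading binarizes at a configurable threshold
(default: any value strictly greater than 0 becomes 1).

**Resampling** between grids is nearest-neighbour only: each target voxel
centre is mapped to world space and takes the value of the nearest source
voxel centre; target voxels falling outside the source field of view get 0.
Nearest neighbour is the only defensible interpolant here — anything else
would manufacture non-binary mask values or parcel labels that exist nowhere
in the source. The implementation composes the two affines and evaluates
`scipy.ndimage.map_coordinates` at order 0 with zero fill. One convention is
worth noting: points inside the outer half-voxel shell (continuous source
coordinate in `[-0.5, 0)` or `(s-1, s-0.5]`) are considered *inside* the
field of view, since they lie within a voxel's physical extent; some other
resamplers clip at the last voxel centre instead. The test suite compares
against nilearn's nearest-neighbour resampler on the interior where the two
conventions coincide.

## Overlays and the common lesion

Counts are summed as integers and divided once by the cohort size, so every
proportion is an exact multiple of 1/n and the `≥ τ` comparison operates on
exact rationals. This matters at the boundary: with n = 39 the attainable
fractions straddle 0.80 (32/39 ≈ 0.8205 vs 31/39 ≈ 0.7949), and with n = 5
a voxel at exactly 4/5 = 0.80 must survive an inclusive threshold. The
default common-lesion threshold is 0.80; `τ = 0` is interpreted as "any
lesion" (voxels with zero coverage are never part of a lesion map).

## Subtraction map and the max-difference threshold

The subtraction map is the voxelwise difference of the two cohorts'
proportion maps (patients minus controls). The binarization threshold is not
a constant of the method: it is *derived from the data* as the difference
between the two global maxima, `τ* = max(p_A) − max(p_B)`, and applied
inclusively (`d ≥ τ*`). Implementing the rule rather than a fixed 0.55 makes
it reusable on any pair of cohorts; 0.55 is simply what the rule yields when
the peaks are 0.97 and 0.42. A negative `τ*` (controls overlap more at their
peak than patients at theirs) is mathematically legal and is allowed with a
warning rather than an error.

A useful consequence of the inclusive rule: any voxel lesioned in *every*
patient sits at `p_A = 1 = max(p_A)`, so its subtraction value
`1 − p_B(v) ≥ 1 − max(p_B) = τ*` always survives. Planted-core recovery in
the synthetic scenario is therefore exact by construction, for every seed —
a property the acceptance tests rely on.

## Parcel overlap

Percentages are parcel-normalized: `100 · |parcel ∩ map| / |parcel|`. The
alternative (lesion-normalized) cannot produce near-ceiling values for small
regions inside a large lesion, which is the regime this analysis is designed
to report. Background label 0 is not a parcel; every nonzero label declared
in the lookup table gets a row (including 0% and empty-parcel rows), so
tables from different maps align. Output rows are sorted by descending
percentage with ties broken by ascending label, making output deterministic.
When the map and atlas grids differ, the map is resampled onto the *atlas*
grid first, so percentages are always computed in atlas space.

## Disconnection index

The index is streamline-count based: the percent of a bundle's streamlines
that make any contact with the lesion. Contact is decided by subdividing
each polyline segment to at most half the smallest voxel edge, mapping each
sample point world→voxel through the inverse affine, rounding to the nearest
voxel index, and testing the mask. The half-voxel step guarantees that no
lesion a full voxel thick can be stepped over, at modest cost; any-contact
(rather than a minimum overlap length) is the convention adopted here, and
it reproduces the 0%/100% endpoints exactly. The index is invariant to point
order reversal and to duplicating every streamline; enlarging the lesion can
never decrease it. Exact equivalence with a dense-walk oracle holds for
axis-aligned straight streamlines; for oblique trajectories grazing voxel
corners the half-voxel sampling may (by design) miss sub-half-voxel contacts,
so the suite checks one-sided agreement there (no false positives).

Parcel-to-parcel disconnection matrices are deliberately not implemented;
only tract-level indices are produced.

## Synthetic data

The generator emulates the contrast the pipeline is built to detect:

- **patient-like cohort** — default n = 39, every subject's lesion is the
  union of a fixed core sphere (radius 18 mm) and a personal sphere with
  radius 37.5 ± 4 mm (≈ 220 cc, matching large peri-sylvian infarcts) and
  4 mm centre jitter;
- **control-like cohort** — default n = 41, no core, radius 24 ± 6 mm
  (≈ 60 cc) with 14 mm jitter: smaller and scattered.

All Gaussian draws (jitter, radii, streamline offsets) are truncated at
three standard deviations and radii floored at 2 mm. Truncation gives every
cohort a *hard* spatial envelope — centre jitter plus radius cannot exceed
`3·jitter_sd + radius_mean + 3·radius_sd` — so geometric statements such as
"the far-corner probe bundle can never touch any analysis map" hold for
every seed, not just typical ones. Each cohort consumes a single
`default_rng(seed)` stream in a documented order (core-inclusion Bernoulli
draws first, then centre offsets, then radii), which lets recovery tests
replay the exact draws independently.

Parcellations are Voronoi partitions around seeded sites. The default
scenario uses a jittered-lattice site set (16 mm spacing, 1.5 mm truncated
jitter) with one site pinned to the core centre, so the core territory
always owns a compact parcel that the recovered map covers at 100%. Tract
bundles are corridors (polylines in mm) with a constant truncated-Gaussian
offset per streamline, so straight corridors give straight streamlines and
geometric hit counts are computable in closed form.

The default grid is 64³ voxels at 2 mm isotropic — small enough that a full
two-cohort pipeline runs in a few seconds, large enough for non-trivial
parcellations and tract geometry.

**What the synthetic data does not emulate:** real vascular-territory
shapes (lesions are spheres, not middle-cerebral-artery distributions),
anatomically shaped parcels, curved tract anatomy, registration error, or
partial-volume effects at lesion borders. Passing tests therefore verify
the *arithmetic and geometry* of the pipeline exactly, but say nothing about
tracing quality or normalization accuracy on real patient data, and real
overlap percentages will reflect those upstream factors.

## Pipeline

`run_pipeline` executes from files on disk to files on disk: overlays
(counts + proportions) per cohort, the common lesion of cohort A, the
subtraction map and its binarization, then both analysis maps (common lesion
and binarized subtraction map) are pushed through both quantifiers — two
parcel-overlap tables and two disconnection tables. The run report (JSON)
records every parameter, derived threshold, map maximum and a sha256
checksum per product; timestamps are excluded so identical configurations
produce identical reports. A stage failure aborts with a stage-named error,
retains the products already written, and marks the report `FAILED` with the
stage name.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
10³-voxel grids for brute-force oracle equivalence (100 random cohorts
checked voxel-by-voxel against triple-loop tallies), 8³ grids for the
20-seed monotonicity sweeps, and the 64³ default scenario (39 + 41 subjects)
for end-to-end recovery. These sizes keep a full verification run under a
minute while exercising every code path at realistic voxel counts per
parcel and streamlines per bundle.

## Known limitations

- No voxelwise inference (VLSM, permutation testing): the subtraction
  approach is deliberately descriptive.
- No nonlinear spatial normalization or native-space registration; inputs
  must already share (or be resamplable to) a common space.
- Nearest-neighbour resampling quantizes partial-volume information away;
  that is intentional for binary masks and labels but makes sub-voxel
  overlap precision unattainable.
- The disconnection index weights every streamline equally; no streamline-
  density or length weighting is applied.
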