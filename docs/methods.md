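# Methods

## Coordinate model

All modules share one frame: continuous, 0-based voxel coordinates
(x = lateral, y = rostrocaudal increasing rostrally, z = dorsoventral) on
an isotropic grid, 39 µm per voxel by default (the Waxholm rat
resolution). A point inside voxel (i, j, k) satisfies
floor(coord) = (i, j, k), so integer coordinates from published tables
address voxels directly while anchored points keep sub-voxel precision.
Distances in µm are always `voxel_units × voxel_size_um`; nothing else in
the package carries units.

Volume orientation is declared once at load time via an explicit axis map
(permutation + flips) rather than inferred from NIfTI headers, because
header conventions differ between atlas distributions and an explicit map
is testable.

## Section anchoring

A section image is the oriented plane `p(px, py) = o + (px/W)·u +
(py/H)·v` with `o` at the image's top-left corner and pixel coordinates
normalized by image width/height. `u` and `v` are not required to be
orthogonal or equal-norm: shear and anisotropic scale absorb oblique
cutting planes and tissue distortion. The inverse map solves the 2×2
normal equations of the orthogonal projection and returns the
perpendicular residual, so "how far off this section was this point" is a
first-class output. Nominally coronal anchors are built from a
rostrocaudal origin level plus two tilt angles implemented as shears
(`scale·tan θ`), which makes the widest-section error formula
`width·tan θ` exact within the model: one degree of lateral-plane
deviation displaces the far edge of a 16 mm section by ≈ 279 µm
rostrocaudally. Assumption: within one section, the mapping is affine —
nonlinear within-section warps are out of scope.

## Density segmentation

The region rule is deliberately literal: mirror the reference neurons
across the sagittal midline (the target nucleus is bilateral, reference
labelling unilateral), compute for every dorsoventral level a disc-count
density on the 1-voxel grid — cell (i, j) counts points with
floor(z) = level and (x−i)² + (y−j)² ≤ r² — and keep voxels whose count
strictly exceeds the threshold (defaults r = 10 voxels, threshold 2,
i.e. ">2 neurons per 10-voxel radius"). Stacking levels yields a filled
boolean mask; contour polylines, if ever needed, are its boundaries. The
epicenter is the unweighted centroid of mask voxels (continuous, plus a
rounded variant); for a bilateral mask the one-sided epicenter comes from
`half_mask`. The centroid-of-mask convention (rather than
centroid-of-contained-points) was chosen because the mask is the
published object; both are one line apart for anyone who prefers the
other.

Cylinder regions take a half-open µm interval measured *along a stated
direction* from a reference rostrocaudal level (default: caudal), so a
[0, 600) µm caudal span at 39 µm voxels covers ⌈600/39⌉ = 16 levels
including the reference level. Flooring to voxel levels is deterministic
and documented rather than clever.

## Quantification conventions

Every point is assigned to exactly one atlas label (its containing
voxel's); background and out-of-volume points go to an explicit
"unassigned" bucket, so per-animal and pooled counts always conserve the
total. Percentages use the full denominator including unassigned —
conservative by construction. Density-segmented or cylinder masks are
reported as *overlay* rows because they overlap atlas labels; they never
enter the conservation sum. Cohort statistics follow the descriptive
mean (min–max) convention appropriate for n = 4 animals; no inferential
statistics are attempted. Medians of even-sized samples are the midpoint
of the central pair. Laterality classifies points by the sign of
x − midline; the ipsilateral side is the majority side of each animal's
starter neurons, and points within 0.5 voxel of the midline are excluded
as indeterminate.

## Clustering

Lloyd k-means with squared Euclidean distance in voxel units (isotropic
grid, so the global µm scale cancels in the variance ratio), best of 25
restarts by default, deterministic given a seed; the Lloyd iterations
come from scikit-learn. The elbow scan additionally warm-starts each k
from the best (k−1) solution plus a split of its widest cluster (its
farthest member becomes a new centroid), and keeps the better of warm
start vs fresh restarts — this guarantees the percentage of variance
explained is non-decreasing in k. If the total sum of squares is zero
(all points identical) the model reports 100% with a `degenerate` flag.

Elbow detection is the maximum-chord-distance rule: the interior k whose
(k, %variance) point lies farthest from the chord joining the curve's
endpoints, ties toward smaller k. A caveat discovered while validating
it, and worth stating plainly: on variance curves of spatially
hierarchical data — e.g. a brain-wide input map whose dominant structure
is the rostrocaudal split between medullary and more rostral sources —
the best 2–4 cluster partitions already capture a large share of
variance, so the chord rule lands at the coarse partition scale (k ≈ 5
on the default synthetic cohort) rather than at the generative component
count. We were unable to construct any 12-component 3D Gaussian mixture
whose k-means variance curve puts the chord-rule elbow at 12, including
leverage-balanced hub-and-satellite geometries built for that purpose;
the rule recovers the breakpoint only of curves that actually have one
(which is unit-tested). The package therefore always emits the full
curve, and every driver accepts an explicit `--k`, mirroring how k is
fixed by inspection in practice.

## Synthetic cohort

The generator's defaults encode the study conditions the package was
built around: 4 mapped animals with (220, 237, 280, 561) input neurons
(total 1298), starters (19, 31, 35, 67) with 40% C1, 273 TH⁺ bulbospinal
reference neurons from 6 reference animals, a 77% ipsilateral bias
applied as a per-point contralateral flip (x → 2·midline − x with
probability 0.23), and a 12-component Gaussian mixture of input sources.
The mixture geometry was designed once, against the cohort's target
marginals — median distance to the epicenter ≈ 2.5 mm, ≈ 10% of inputs
beyond 5 mm, ≈ 92% of inputs in brainstem-group regions with ≈ 3% each
in midbrain and forebrain, ≈ 86% reference-cloud containment, and ~90%
variance explained at k = 12 — and then frozen; components sit on an
inner (~1.7 mm) and outer (~2.7 mm) radial shell around the epicenter
plus pontine, parabrachial, midbrain and hypothalamic satellites, all on
the ipsilateral side, with the contralateral population arising entirely
from the flip. The TH⁺ reference cloud is an anisotropic Gaussian
(σ = 6.5, 7.5, 4.5 voxels), a dorsoventrally flattened ovoid like the
nucleus it stands in for; an isotropic σ = 8 cloud leaves ~36% of its
points outside the density mask and was rejected for that reason.

The toy atlas is a brainstem tube (elliptical cross-section, y-span
12–262) with nested bilateral RVLM and facial-nucleus ellipsoids, plus
midbrain/forebrain/cerebellum blocks and a spinal-cord stub — enough
structure for regional counting to have non-trivial ground truth, with
no pretence of anatomical fidelity.

Virtual sectioning cuts each animal's cohort into parallel near-coronal
planes: one cutting angle per animal drawn from ±3° by default (the
blocked brain is mounted once; per-section jitter is available and
defaults to 0), plane spacing equal to the 50 µm section thickness, each
neuron assigned to its nearest plane and projected to pixels through the
anchoring model. Parallel planes at thickness spacing bound the
round-trip error by half a thickness (≈ 0.64 voxel), which the tests
assert up to ±10° tilts. Features of real data deliberately *not*
emulated: detection sensitivity differences between imaging modalities,
within-section nonlinear distortion, sparse imaging of every n-th
section (it would discard ground truth), and anatomically shaped
nuclei. Passing tests therefore demonstrate the pipeline's geometric and
statistical correctness, not robustness to imaging artefacts.

## Numerical choices

- Strict `> threshold` density comparison (printed rule is ">2").
- Disc membership uses ≤ on the squared radius; a zero-diameter cylinder
  is empty by convention.
- Label lookup floors coordinates; out-of-bounds lookups return
  none/unassigned rather than raising.
- CSV round trips read floats with `float_precision="round_trip"` so
  written coordinates re-read bit-identically.
- Cluster ids are 1-based in every output table.
- All synthetic randomness flows from one integer seed through a single
  `numpy` generator; k-means seeds derive from the same integer.

## Known limitations

- Clustering pools animals, so cluster composition is dominated by the
  largest cohort member; the per-animal composition columns in
  `cluster_table` make this visible but do not correct it.
- The chord-rule elbow is a reproducible surrogate, not a substitute for
  judgement on hierarchical data (see above).
- The midline is a single sagittal plane; brains with curved midlines
  would need a per-level midline, which the API does not model.
- Region groups (brainstem/midbrain/...) are configuration, not code:
  atlas releases differ in label inventories, so group membership ships
  in the label table / YAML config rather than being hard-coded.
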