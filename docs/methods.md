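# Methods

## Model and procedure

`seegseg` treats the thresholded post-implant CT as an intensity function
`I(x, y, z)` sampled at voxel centers; all geometry is carried out in
physical millimetres (voxel indices mapped through the NIfTI affine), the
only scale at which "a 3 mm region" is meaningful for anisotropic voxels.
A voxel belongs to the cubic region `R(c, l)` iff each coordinate of its
center is within `l/2` of `c`, boundary inclusive; regions are clipped at
the volume border rather than erroring, because head-search regions near
the skull routinely touch it.  Electrode metal is defined by the strict
test `I > S`; a voxel exactly at `S` is background.

Localization composes two primitives:

* **Significant-voxel search**: growing cubes (default 3 mm, +1 mm steps)
  around a query point; within the first non-empty cube the
  above-threshold voxel *nearest a preference point* is taken (ties by
  C-order, hence deterministic).  Nearest-to-anchor rather than raw scan
  order matters in one place: the first contact search starts half a
  pitch from the tip, exactly between contacts 1 and 2, and anchoring to
  the tip resolves that ambiguity to contact 1 regardless of shaft
  orientation.
* **Centroid refinement**: iterate `c ← com(R(c, side))` (mass from
  voxels above `S`) until the step is below `eps`.  On an isolated blob
  the map is contractive and converges in a few iterations; the fixed
  point is the blob's thresholded mass centroid.

Per electrode the algorithm estimates the head `H` (screw centroid near
the planned entry; failure if nothing significant lies within 10 mm),
follows the shaft head→tip with step `d` = contact pitch re-deriving the
direction from the last two accepted points (piecewise-linear axis), and
finally walks tip→head collecting contact centroids, numbered from the
tip.  Only the *direction* of the planned target is used, which is why
the result is insensitive to target displacement: after the first
accepted axis point the walk is locked to the imaged shaft.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `threshold` | auto | histogram first-minimum; clinical CBCT practice uses 1600 |
| `region_side` | 3 mm | refinement cube: larger than the 2 mm contact, smaller than the 3.5 mm pitch |
| `head_l_init..l_max` | 3→10 mm | growing search around the planned entry |
| step `d` | model pitch (3.5 mm) | natural scale of the shaft; shared by axis-following and contact collection |
| `tail_reach_factor` | 1.5·d | cap on the growing search while following, so a lost tip cannot leap to a neighbouring shaft |
| `max_angle_deg` | 10° | empirical bound on true inter-contact bends; larger implied bends signal merged metal |
| `shrink_step` | 0.5 mm | region-shrink schedule under the angle constraint |
| `eps` | 1e-3 mm | centroid fixed-point tolerance (convergence is geometric; <10 iterations typical) |
| `max_iter` | 50 | refinement safety cap |
| `min_advance_factor` | 0.5·d | stalled-step criterion: a candidate closer than d/2 to the previous point means the walk re-found the last blob — the tip |
| `plane` | None | hemisphere guard; off unless a fissure plane is supplied, since a default mid-sagittal plane is meaningless for corner-origin affines |

The stalled-step criterion is this implementation's concrete version of
"stop when the tip is reached": beyond the tip the growing cube can
still reach back to the last contact's blurred halo, and without the
criterion the walk would oscillate there.

The angle constraint accepts bends up to 10°, which geometrically allows
a lateral play of `d·tan 10° ≈ 0.62 mm` per step; at a genuinely merging
crossing the constrained estimate therefore lands within ~0.5 mm of the
true contact rather than at the merged-blob centroid (>1 mm off).  A
physical bend at exactly the limit can measure slightly above 10°
through voxel-quantization noise; the shrunken-region estimate is kept
and flagged (`merged`) rather than dropped.

The hemisphere guard stops the walk when a candidate lies strictly on
the opposite side of the fissure plane from the head point.  A pure
distance-difference formulation would also stop long electrodes running
parallel to the fissure, so the side test is used.

Automatic thresholding smooths a 256-bin histogram of the positive
intensities (5-bin moving average) and takes the first interior local
minimum that has descended below half the running maximum; the
prominence requirement keeps sampling wiggles inside the background mode
from being mistaken for the valley.  Monotone histograms raise an error
asking for a manual `S`.

## The phantom generator

`seegseg.phantom` builds synthetic post-implant volumes with exact
ground truth: anisotropic voxels (0.4, 0.4, 0.8 mm), anti-aliased
cylinder rasterization (3³ sub-voxel coverage sampling), a spherical
screw blob at each entry, a Gaussian metal-artifact blur (σ = 0.4 mm)
that merges nearby contacts, and seeded sub-threshold uniform noise.
Shafts may bend, cross, or share one axis bilaterally.

Source intensities are chosen so the *thresholded* phantom looks like
the clinical case the method assumes.  The blur conserves mass, so a
0.8 mm-diameter cylinder dims by a factor ≈ 0.39, and a contact whose
cross-section straddles two 0.8 mm voxel layers loses another factor
≈ 2 to partial volume.  With the default pre-blur intensity of 10000
the post-blur contact cores sit near 3900 — the metal-vs-1600-threshold
regime of real cone-beam CT — and the worst-case straddling contact
stays comfortably above `S` (~2100).  A consequence shared with real
scans: the apparent (above-`S`) contact is somewhat larger than the
physical cylinder; the rasterizer itself is validated by exact mass
conservation (coverage sum × voxel volume = analytic metal volume).

Ground truth is the mass centroid of each contact's *own blurred
rasterization* (voxels above `S`), not the ideal cylinder center: the
algorithm can only ever recover image mass, and this separates
rasterization error from algorithm error.

What the phantom does **not** emulate: beam-hardening streaks and
direction-dependent artifacts, brain-tissue texture, bone residue after
imperfect subtraction, registration error between planning and CT
space, and gain/scale variation between scanners.  Passing phantom
tests therefore demonstrates the geometric correctness and robustness
of the search logic under the stated imaging model, not performance on
any particular scanner's output.

## The displacement experiment

For each phantom implant a baseline segmentation from the true planned
fiducials is compared with runs whose targets are all displaced by a
fixed radius on the circle perpendicular to the entry–target axis
(uniform random angle, seeded).  Robustness is the *paired* per-contact
distance to the baseline run, matched by electrode label and contact
index; accuracy against ground truth is reported separately as FP/FN
counts under greedy nearest matching within half a pitch (1.75 mm —
beyond that a detection is ambiguous between neighbours) normalized by
the total true contact count.  The shipped experiment uses five implants
of ten straight electrodes (8–18 contacts), radii 1–12 mm (and an
8-radius grid to 15 mm), five samples per radius — sizes at which the
whole study runs in well under a minute on one CPU while every electrode
geometry class (8–18 contacts, tilted shafts) is exercised.

On these phantoms the displaced runs are bitwise identical to the
baselines: the first axis step always re-finds the same screw-adjacent
contact, after which the walk depends only on the image.  The reported
mean paired errors are therefore exactly zero, and FN/FP remain zero
even at 15 mm; errors would first appear for displacements large enough
to break the first-step lock (beyond ~2.6 mm of lateral miss at the
first search cube, i.e. far larger target errors or much shorter
electrodes than occur clinically).

## Known limitations

* Entry and target must be plausible to within the 10 mm head search;
  grossly wrong fiducials fail an electrode (recorded per label, never
  aborting the implant run).
* Shafts closer than about the refinement region (3 mm) over a
  sustained stretch can capture each other's walks; the angle
  constraint protects point crossings, not near-parallel merges.
* The contact count stops at the supplied model's `N`; without a model
  the walk runs to signal loss and may include the screw-adjacent
  artifact on some scanners.
* Inputs must be co-registered on one grid; no resampling or
  registration is performed.
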