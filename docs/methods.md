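# Methods

This note documents the models, conventions and numerical choices behind
`lumenmetry`, including the design decisions that were genuinely open and
the known limitations of each stage.

## Coordinates, units, calibration

Arrays are indexed `(z, y, x)`, 0-based, ascending z; voxel `(z, y, x)`
sits at physical `(z·Δz, y·p, x·p)` µm, where `p` is the lateral pixel
size and `Δz` the axial step (default 5 µm, the standard confocal step for
cleared microtissues at 20×).  All lengths/areas/volumes are µm/µm²/µm³.
Physical lengths convert to pixels by half-up rounding with a floor of
1 px for any positive length, so a nominally non-zero structuring element
is never a no-op.

## Channel fusion

The nuclei ("cells") and actin ("walls") channels are each min–max
normalized per slice and combined pixelwise (max by default; a
re-normalized weighted sum is available).  A constant channel normalizes
to all-zeros rather than erroring, so blank slices flow through the
pipeline.  The mapping cells=nuclei, walls=actin is configurable: the two
stains are the conventional Hoechst/phalloidin pair, but nothing else in
the pipeline depends on their identity once fused.

## Binarization

Foreground = pixels above the between-class-variance-maximizing (Otsu)
threshold of the slice, computed after Gaussian smoothing with σ = 1 px
(configurable; a fixed threshold is available).  Constant slices are
all-background.  Two caveats worth knowing:

* the threshold is global per slice; with a large dark background and a
  bright cell mass it sits between the two modes, but smoothing plus
  threshold placement systematically erodes small dark voids by roughly
  half a pixel of radius — visible as a ~10–20 % area deficit for voids of
  ≤ 5 px radius;
* slices containing only noise (above/below the spheroid) binarize into
  speckle; the resulting spurious candidates are cheap and are removed by
  the classifier, not by ad-hoc gating.

## Iterative closing and void extraction

Closing (dilation then erosion) uses a disk of pixel radius
`round(r_µm / p)`; the "disk size" schedule `6, 11, …, 41 µm` (start 6 µm,
increment 5 µm, 8 iterations) is interpreted as **radius** — the most
common structuring-element convention; a diameter mode exists because the
convention is genuinely ambiguous.  The image is padded by the radius
before closing, making the operation exactly the unbounded closing
restricted to the frame; this is what makes the implementation agree
bit-for-bit with a naive shift-based oracle, and gives extensivity and
idempotence exactly.

Voids are 4-connected components of the background phase (foreground is
8-connected — the standard complementary pairing).  The single largest
background component is removed (ties break to the smallest label); an
optional border filter exists but is off by default, since largest-only
rejection is the faithful rule.  Candidates below 25 µm² (configurable)
are discarded as noise specks.

Superimposition across iterations merges candidates whose masks share at
least one pixel (transitive closure) and keeps the maximum-area member of
each class — larger disks shrink the same void in place, so the earliest
sealing iteration holds the largest, least-distorted form.  Ties break by
iteration then label, so the whole phase is deterministic.

## Patch preparation and classification

A candidate's bounding box is dilated by 5 µm (so the classifier sees the
wall), clipped, min–max remapped, zero-padded to square and resampled to
64×64.  The padding margin and the interpretation of "remapping" as
intensity rescaling were open choices; both are documented defaults, not
tuned values.  The 64 px side keeps the default classifier desk-scale.

The classifier is an interface with four backends:

* **trained** (default for end users): `HistGradientBoostingClassifier`
  over rotation-invariant features — a 10-bin radial intensity profile
  plus center mean, outer-ring mean, their contrast, global mean and SD.
  Training takes an explicit seed, uses an 80/20 stratified split and
  reports held-out accuracy.  Tree boosting over engineered features was
  chosen over a CNN: at 64×64 patches and a few hundred labels it is more
  data-efficient, CPU-cheap and fully deterministic.
* **heuristic**: `p = σ(−4 + 2.5·(1−interior) + 2·solidity +
  3·clip(rim_contrast, −1, 1))`, with features measured on the fused
  slice (rim = 5 µm dilation ring).  The coefficients are fixed by
  construction so that an ideal dark, solid, bright-rimmed void scores
  > 0.9 and a contrast-free ragged region scores < 0.5.  It is a
  baseline: rimless-but-contrasty artifacts can fool it.
* **oracle**: ground-truth lookup (candidate is true iff ≥ 50 % of its
  pixels lie in a true void); isolates detection/volumetry errors from
  classification errors in tests.
* **constant**: fixed probability.

Models serialize to a single pickle file with a format/version header;
round-trips preserve predictions bit-exactly.

## Grouping and 3D reconstruction

Accepted 2D lumens on different slices join the same group when their xy
bounding boxes intersect and their z-distance is ≤ `max_gap + 1`
(`max_gap = 0` by default — the strictest reading: any missing slice
splits, because a gap most probably separates vertically stacked lumens;
the parameter exists because a 5 µm step can skip a thin waist).
Connected components are then split at gaps wider than `max_gap`.
Grouping is a partition, and increasing `max_gap` can only merge groups.

**Point cloud.**  Each optical section stands for a slab of thickness Δz.
A member contributes the midpoints of its exposed void-pixel edges — the
polygonal boundary of the union of void-pixel squares, whose enclosed
area equals the pixel-count area (sampling pixel centers instead biases
the radius half a pixel inward; sampling corners half a pixel outward) —
at its section plane `z·Δz`; the terminal members repeat their rings half
a slab outward (`z ∓ Δz/2`).  The reconstructed solid then interpolates
linearly between section planes (a trapezoid-rule profile) and extrudes
the end sections over their half-slabs, which converges to the
single-slice extrusion convention for one-member groups.  This layout was
chosen over duplicating every ring at both slab faces: coincident ring
pairs at internal interfaces force the Delaunay complex to bridge
reentrant annular steps, a positive bias that reached +20 % for
vertically short lumens, whereas plane placement keeps the profile error
within a few percent across the 10–30 µm void range.  Clouds above
20 000 points are subsampled with a fixed seed.

**Alpha shape.**  The alpha complex keeps Delaunay tetrahedra of
circumradius ≤ α.  For a boundary-sampled solid the kept tets form a
crust; the *enclosed* volume additionally counts cavity tetrahedra
unreachable from the hull exterior through non-kept tets (a flood fill
over the Delaunay adjacency).  `alpha="auto"` picks the smallest
circumradius threshold whose kept complex (i) covers every point, (ii) is
one face-connected region, and (iii) is *sealed*: the enclosed region must
contain the cloud centroid, which rejects leaky crusts — for the convex-ish
voids in scope the cavity drains or fills as a whole.  Volume is the summed
tet volume of the enclosed region; the surface is the triangle set
separating it from outside.  Degenerate clouds (fewer than 4 non-coplanar
points) fall back to per-member extrusion with a logged warning.
Residual errors are dominated by the binarization shrink of the smallest
voids (negative, up to ~15 % of volume at 5 px radius) and the trapezoid
profile (±2 %); a digitized ball of r = 10 z-steps reconstructs to within
~2 % of its analytic volume.  Volumes are comparable within a
configuration, not across implementations.

Single-slice groups use extrusion: `V = area·Δz`,
`A = 2·area + perimeter·Δz`.

## Synthetic data

The generator renders what the pipeline actually consumes: a bright
spheroid (actin = continuous wall texture 0.85 ± 0.05, nuclei = speckled
dots 0.92, background 0.03) with dark axis-aligned ellipsoidal voids, on a
176×176 px field at 2 µm/px, 36 slices at 5 µm — a ~160 µm spheroid, the
scale of a 256-well hydrogel microtissue.  Gaussian intensity noise
(σ = 0.05 by default) is added to both channels.  Archetypes:

* **true lumen** — fully rimmed ellipsoid, semi-axes drawn 10–30 µm,
  placed with ≥ 12 µm of wall to the spheroid surface; optionally one
  lumen per stack carries a boundary gap (5–10 µm corridor to the outside)
  that only a sufficiently large closing disk can seal;
* **dimhole** — an in-shell void whose surrounding actin is locally dimmed
  to 0.35: binarizes as an enlarged enclosed void without a true bright
  rim (false lumen);
* **pocket** — a debris ring (0.55) outside the shell enclosing plain
  background (false lumen).

Ground truth carries per-void labels, per-slice masks, and analytic
ellipsoid volumes (4/3·π·a·b·c); expected totals count true lumens only.
All randomness flows from the spec seed through spawned per-slice
generators, so output is bit-identical for identical specs.

What the generator does **not** emulate: PSF blur, depth attenuation,
anisotropic optical sectioning, touching spheroids, non-ellipsoidal
(lobed, branched) lumens, and staining heterogeneity beyond the uniform
texture.  Passing tests therefore demonstrate correctness of the stated
rules and the volumetric estimator on geometrically clean data — not
segmentation robustness on real microscope images, where threshold choice
and wall discontinuities are harsher.

## Problem sizes and defaults

The test suite and the acceptance script run the study conditions at
desk scale: 20 randomized stacks (1–4 true lumens, 0–2 decoys each) for
geometry recovery, a balanced n = 200 patch set from 8 stacks for
classifier training, 60 random 64×64 masks for the morphology oracles,
and gap widths {2, 6, 10, 20, 30} µm for gap-closing equivalence.  These
sizes give stable statistics for every property checked while keeping a
full run in minutes on one CPU.

## Known limitations

* Voids smaller than the first closing disk (≈ 6 µm radius) are filled by
  every iteration and cannot be detected — inherent to the closing-based
  approach, which bounds the detectable size from below.  The same floor
  removes the *terminal cross-sections* of larger lumens: a 10–12 µm
  lumen loses its top and bottom sections (≲ 6 µm radius) and with them
  10–15 % of its volume, so a stack whose only lumen sits at the small
  end of the range can miss the ±15 % band even though counts stay
  exact.  Recovery within ±15 % is reliable for lumens with smallest
  semi-axis ≥ ~12 µm at a 5 µm step.
* The heuristic backend over-accepts contrast-rich artifacts; it is a
  labeled-data-free baseline, not a substitute for the trained backend.
* The alpha-shape auto parameter assumes one convex-ish cavity per group;
  strongly non-convex lumens would need a fixed, smaller alpha chosen by
  the user.
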