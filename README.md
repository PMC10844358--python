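# lumenmetry

Automated lumen identification, 3D reconstruction and volumetry for
two-channel fluorescence z-stacks of 3D microtissues.

Glandular epithelial structures — mammary spheroids and acini, organoids of
secretory organs — form internal fluid-filled cavities (lumens).  Lumen
count and total luminal volume are biologically meaningful readouts of
differentiation and of endocrine (estrogenic) stimulation, but in
high-content z-stacks a lumen is just a dark void with the same intensity
class as the background, often connected to it through gaps in the imperfect
cell wall.  `lumenmetry` turns stacks of optical sections (nuclei/Hoechst +
F-actin/phalloidin channels, fixed z-step, default 5 µm) into per-microtissue
reports: the number of lumens and the volume and surface area of each.

## Method

For each z-slice the fused (per-channel min–max normalized, pixelwise max)
image is binarized with an automatic between-class-variance threshold after
light Gaussian smoothing.  Morphological closing with a disk structuring
element seals gaps in lumen boundaries; because a single disk size cannot
seal wide gaps without destroying small lumens, closing is repeated with a
schedule of growing radii — r₀ = 6 µm, Δr = 5 µm, 8 iterations, i.e.
disks of 6, 11, …, 41 µm.  After each closing, 4-connected components of
the *background* phase are extracted and the single largest one (the true
outside background) is discarded; the rest are candidate voids.
Superimposing all iterations keeps exactly one copy of each physical void,
at its largest detected form (larger disks shrink the same void in place).

Each candidate is cut from the fused image as a margin-dilated, intensity
remapped, S×S patch and scored by a pluggable classifier
(P(true lumen) ∈ [0, 1]; accept iff ≥ threshold):

* **trained** — gradient-boosted trees on rotation-invariant radial-profile
  features, trained on labeled patches (synthetic or user-labeled archives);
* **heuristic** — a fixed logistic score over interior darkness, solidity
  and rim contrast;
* **oracle / constant** — testing backends.

Accepted 2D lumens are grouped across slices by vertical bounding-box
overlap; a run of slices with no member splits the group (several stacked
lumens).  Each group's void-pixel boundary, sampled at the exposed pixel
edges on both faces of each slice's z-slab, becomes a physical point cloud
whose **alpha shape** (circumradius-filtered Delaunay complex; auto-alpha =
smallest alpha giving one connected, sealed, all-point-covering region)
yields the enclosed volume V (µm³) and surface area A (µm²).  Single-slice
lumens use the extrusion convention V = area · Δz.

A fully ground-truthed synthetic generator renders spheroid stacks with
ellipsoidal true lumens (analytic volume 4/3·π·a·b·c), boundary gaps, decoy
voids (rimless holes, exterior debris pockets) and noise, so every stage is
verifiable without external data.

## Worked example

```python
from lumenmetry import (
    OracleClassifier, RunConfig, analyze_stack, generate, random_spec,
)

spec = random_spec(seed=42)              # one synthetic spheroid stack
stack, truth = generate(spec)

clf = OracleClassifier(truth.true_masks)  # ground-truth classifier backend
config = RunConfig(calibration=spec.calibration, seed=42)
report = analyze_stack(stack, config, clf)

print(f"stack {report.stack_id}: {report.lumen_count} lumens, "
      f"total volume {report.total_volume_um3:.0f} um^3 "
      f"(ground truth: {truth.expected_lumen_count} lumens, "
      f"{truth.expected_total_volume_um3:.0f} um^3)")
for lum in report.lumens:
    print(f"  {lum.group.group_id}: z {lum.group.z_min}-{lum.group.z_max}, "
          f"{lum.volume_um3:.0f} um^3, {lum.surface_area_um2:.0f} um^2 [{lum.method}]")
```

Output:

```
stack synthetic-42: 1 lumens, total volume 29400 um^3 (ground truth: 1 lumens, 28575 um^3)
  g000: z 13-20, 29400 um^3, 5135 um^2 [alpha]
```

The stack contains one ellipsoidal lumen of analytic volume 28 575 µm³; the
pipeline detects it on slices 13–20, reconstructs it by alpha shape and
measures 29 400 µm³ (+2.9%, within the discretization error expected at a
5 µm z-step for a ~19 µm void).

## Command line

```bash
lumenmetry simulate --seed 1 --n-stacks 5 --out stacks/   # synthetic OME-TIFFs
lumenmetry detect stack.ome.tif --pixel-size 1.2 --out candidates.csv
lumenmetry train --seed 1 --out model.clf                 # or --patches-dir/--labels
lumenmetry analyze stack.ome.tif --pixel-size 1.2 --classifier model.clf --out report.csv
lumenmetry batch stacks/ --pixel-size 1.2 --out results/  # per-condition summary CSV
```

The xy pixel size is not stored in all acquisition exports and must be
supplied (`--pixel-size`, µm/px); the z-step defaults to 5 µm.

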