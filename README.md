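# ctsa — CT-based spatial analysis of implant migration

`ctsa` measures the six-degree-of-freedom migration of an unmodified,
monobloc implant relative to radiopaque marker beads embedded in the
surrounding bone, from a pair of ordinary low-dose CT scans. It targets the
validation problem faced before using such a method clinically: how
accurately and how repeatably can implant motion be measured when the
implant itself cannot carry markers (an all-ceramic hip resurfacing head
and cup) and the only landmarks are ~1 mm tantalum beads in the pelvis and
femur? The package ships the full measurement chain, a digital
bead-and-implant phantom that stands in for the physical motion-stage rig,
and the statistics used to qualify a migration method (precision, accuracy,
Bland–Altman agreement, observer reproducibility).

It is intended for researchers developing or validating CT-based migration
(micromotion) analysis — the CT counterpart of roentgen stereophotogrammetric
analysis (RSA).

## Method

Given a *reference* and a *target* scan, the measurement runs in six stages:

1. **Segmentation** — threshold + 26-connected components; bead-sized
   components (volume within [0.2×, 3×] of a 1 mm sphere) are markers, the
   largest remaining component is the implant construct; scatter radiating
   from the implant surface is removed by a deterministic grey-level and
   morphology rule; the glued head/cup construct is split by radial
   distance from a robustly fitted common centre, and the mating implant is
   discarded.
2. **Bead location** — each bead is reduced to the centre of mass of its
   above-reference grey values, recovering the centre to a small fraction
   of a voxel despite the mask spanning only a handful of anisotropic
   voxels.
3. **Implant matching** — the target implant surface (marching-cubes mesh)
   is registered onto the reference surface: deterministic coarse alignment
   (centroid + principal axes, skewness-disambiguated signs), then
   iterative closest point with exact closest-surface-point
   correspondences and a closed-form rigid update per iteration.
4. **Bead matching** — the implant transform repositions the target bead
   centres; beads are paired by mutual nearest neighbour; the optimal rigid
   transform between the paired sets is the weighted Kabsch/SVD solution.
   The condition number σ₁/σ₃ of the centred marker matrix is reported
   (values above 120 flag a degenerate marker distribution).
5. **Movement decomposition** — the inverse transform (implant motion
   relative to the markers, the clinical convention) is decomposed into
   translations *(tx, ty, tz)* of the implant centre in mm and extrinsic
   X→Y→Z Euler rotations *(rx, ry, rz)* in degrees, about right-handed
   axes X = proximal–distal, Y = medial–lateral, Z = anterior–posterior.
6. **QC** — condition numbers, ICP residual, bead pair count and stage
   flags accompany every result; a flagged stage is never silent.

Validation statistics follow the standard definitions: **precision** =
1.96 × SD of zero-displacement double-measurement readings; **accuracy** =
1.96 × RMS error between imposed and measured motion; Bland–Altman bias and
limits of agreement; a two-sided variance-ratio F-test about the expected
zero error for observer reproducibility; Shapiro–Wilk for normality. CT
dose bookkeeping uses DLP = CTDIvol × scan length and E = k·DLP.

The digital phantom voxelises spherical beads, a hemispherical-shell
head-in-cup construct (with stem and rim lugs — surface matching needs
contoured features, as pure spheres slide tangentially under rotation), and
a low-contrast bone shell at 0.34 × 0.34 × 0.6 mm voxels, with supersampled
partial-volume occupancy, seeded Gaussian noise and an optional streak
artefact model. Migration is simulated as the rig did it: the marker
segment moves around the fixed implant construct.

## Worked example

```python
import numpy as np
from ctsa import (MeasureConfig, MigrationResult, MotionStep,
                  compact_phantom, measure_migration, render_pair)

spec = compact_phantom()                      # reduced study phantom, 10 HU noise
step = MotionStep("tx_1mm", MigrationResult(1.0, 0, 0, 0, 0, 0))
reference, target, truth = render_pair(spec, step, seed=1)

report = measure_migration(reference, target, MeasureConfig.for_phantom(spec))
r = report.result
print(f"t = ({r.tx:+.3f}, {r.ty:+.3f}, {r.tz:+.3f}) mm")
print(f"r = ({r.rx:+.3f}, {r.ry:+.3f}, {r.rz:+.3f}) deg")
print(f"bead pairs = {report.qc.bead_pairs}, "
      f"CN = {report.qc.condition_number_reference:.2f}, "
      f"flags = {list(report.qc.flags)}")
```

prints

```
t = (-0.995, -0.001, +0.001) mm
r = (-0.016, +0.011, +0.032) deg
bead pairs = 9, CN = 1.06, flags = []
```

The markers were moved +1 mm along X around the fixed implant, so the
implant migrated −1 mm relative to the markers: the measurement recovers it
to 5 µm, with sub-0.04° rotation error, using all 9 bead pairs of a
well-conditioned marker cloud (condition number 1.06, far below the 120
warning level).

A full validation study is one call (or one CLI invocation):

```bash
ctsa validate --mode accuracy --seed 1 --out accuracy.json
ctsa dose --ctdi 1.05 --length 16.7 --k 0.015
```

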