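# Methods

## The measurement model

A migration measurement treats two CT scans of the same joint as rigid
scenes: an implant (segmented by its surface, since a monobloc ceramic part
cannot carry markers) and a cloud of ~1 mm tantalum beads fixed in the host
bone. The target scan's implant surface is registered onto the reference
scan's implant surface; that transform carries the target bead centres into
an implant-anchored frame, where the residual rigid motion of the paired
bead clouds is exactly the bone-marker motion relative to the implant. Its
inverse — implant relative to bone, the quantity clinicians track — is
decomposed into three translations of the implant centre (mm) and three
Euler rotations (degrees).

Conventions, fixed once and used everywhere:

* **Axes** — right-handed; X proximal–distal, Y medial–lateral,
  Z anterior–posterior.
* **Euler order** — extrinsic X→Y→Z about fixed axes,
  `R = Rz(rz) @ Ry(ry) @ Rx(rx)`. Any fixed order changes individual angle
  values only for combined rotations; the single-axis motions of a
  validation protocol are unaffected. Gimbal lock (|cos ry| < 1e-6) is
  flagged, never silently resolved; a ±2° migration protocol cannot
  approach it.
* **Reference point** — translations are reported as the displacement of an
  explicit point, by default the centre of the sphere fitted (closed-form
  algebraic fit) to the analysed implant's articulating surface. The fit is
  biased a fraction of a millimetre by the rim annulus, but identically so
  in both scans; ground truth is always decomposed about the same point.

## Pipeline stages and their numerical choices

**Segmentation.** Voxels at or above a threshold (default: midway between
the bone-proxy and implant intensities, i.e. 1850 HU for the default
palette) are labelled with 26-connectivity — 1 mm beads span only 2–3
in-plane voxels, so diagonal adjacency matters. Components sized within
[0.2×, 3×] the nominal bead sphere volume are bead candidates; bead-sized
components closer than 1.5 mm to the implant component are scatter
radiating from the implant surface and are rejected (beads sit in bone,
clear of the implant). The largest remaining component is the implant
construct; a second component above half its size flags an ambiguous
construct. A configurable expected bead count turns silent bead loss (e.g.
a bead fused to the implant by artefact) into a flag.

**Artefact removal.** The deterministic replacement for the operator's
trained eye: implant-mask voxels dimmer than 60% of the mask's median grey,
and voxels that neither survive a 6-connected morphological opening nor
have at least 9 of 26 neighbours in the mask, are removed. Streak rays are
voxel-wide chains and isolated bumps; genuine staircase voxels of the shell
body are solidly attached and survive the neighbour rule. If the rule would
delete more than half the mask the input is returned flagged instead. An
optional manual exclusion list (index boxes) preserves an audit trail for
operator overrides. Beads whose voxels touch a rejected artefact component
are excluded from registration rather than repaired; the marker cloud's
redundancy absorbs the loss.

**Head/cup separation.** The glued construct is split by radial distance
from a common centre fitted to the two shells. Voxels are scored against
the shell *mid-surface* radii with a Cauchy loss (scale = half shell
thickness), seeded by a closed-form algebraic sphere fit. Mid-surfaces
matter: scoring against the outer radii lets an axial shift snap mid-shell
voxels onto the wrong model surface, creating spurious minima that moved
the centre by over a millimetre between repositioned scans. The decision
boundary is the smaller outer radius (the glued interface), so swapping the
configured radii swaps the outputs symmetrically. A median residual above
0.45× the larger shell thickness (legitimate shells sit near thickness/4)
raises a fit-failure error.

**Surface extraction.** Marching cubes at the segmentation threshold on a
crop in which the true grey field is kept around the mask and only bright
non-mask voxels (the removed mating implant) are clamped below the
iso-level. Keeping the genuine sub-threshold grey ramp is essential: an
early version clamped all non-mask voxels to a constant and the surface
landed on voxel boundaries instead of the sub-voxel iso-crossing, leaving a
grid-alignment-dependent 0.25 mm RMS mismatch between repositioned scans.

**Bead localisation.** The bead centre is the centre of mass of
`max(grey − reference, 0)` over the mask's voxel-centre world coordinates,
with the configured bone/background intensity as the reference so the noise
floor does not bias the centroid. On the rendered phantom this recovers a
displaced bead to < 0.04 mm (about a tenth of the in-plane voxel) at
rendering supersampling 5.

**Coarse alignment.** Centroid matching plus principal-axis alignment, with
axis signs disambiguated by the third central moment (skewness) along each
axis — an even moment cannot carry sign information. Near-degenerate
eigenvalues (rotational symmetry, as for a hemispherical cup) or
near-zero skewness fall back to centroid-only translation, flagged; when
the implant has barely moved that is also the correct ICP start. An
operator-supplied initial transform is accepted via config, mirroring a
manual pre-alignment workflow.

**ICP.** Point-to-point iterative closest point on the moving mesh's
vertices with a closed-form (Kabsch) rigid update per iteration and a cost
trace that is provably non-increasing. Correspondences are the exact
closest points on the fixed *surface* (k-d tree over face centroids, exact
point-triangle projection on the six best candidates), not the nearest
vertices: marching-cubes vertices form rings at slice crossings, and
nearest-vertex matching aliases small rotations into ring-to-ring false
minima roughly one slice spacing apart (≈ 2.7° on a 12.7 mm cup at 0.6 mm
slices). Convergence at 1e-4 mm RMS change or 100 iterations; a
non-converged run returns its best transform with `converged=False`. A
deterministic vertex subsample (default 4000 in the pipeline) bounds the
per-iteration cost with no measurable accuracy loss; optional
worst-fraction trimming is available for artefact-clipped meshes and is off
by default.

**Rigid fit between paired beads.** The weighted Kabsch/SVD closed form,
reflection-corrected; with pre-paired beads the closed form is exact, so no
correspondence iteration is run. Mutual-nearest-neighbour pairing is exact
in practice because bead spacing (≥ 8 mm) dwarfs protocol displacements
(≤ 2 mm/2°); a contested target bead within one bead diameter is flagged,
never guessed. The condition number σ₁/σ₃ of the mean-centred bead matrix
is logged together with the raw singular values (so alternative scalings
can be recomputed); 120 is the conventional warning level, and the default
phantom's segments sit near 1–2.

## The digital phantom

The generator replaces the physical motion-stage rig: it voxelises beads
(spheres), a hemispherical-shell head glued inside a hemispherical-shell
cup, and a low-contrast bone shell carrying the marker beads, then moves
the *marker segment* (beads + bone) in continuous space around the fixed
implant before sampling — exactly the rig's inverted kinematics, reconciled
by inversion in the validation harness.

* Voxel grey = background + Σ (material − background) × occupancy, with
  occupancy from cell-centred supersampled point-in-solid tests (default
  5 per axis; boundary voxels only — interior voxels are classified
  analytically). Solids accumulate in priority order so a bead embedded in
  bone reports the bead's intensity.
* Default palette: air −1000 HU, bone proxy +700, ceramic +3000, tantalum
  +3071 (12-bit ceiling); voxels 0.34 × 0.34 × 0.6 mm; Gaussian noise
  10 HU (seeded); streak artefact as bright/dark rays of exponentially
  decaying amplitude (default 1500 HU, 4 mm decay, 24 rays) through random
  implant-surface points, seeded separately so noise seeds share identical
  noise-free content.
* The implant carries a short femoral stem (head) and three rim lugs at
  asymmetric azimuths (cup). These stand in for the real implants'
  contoured rims: nested spherical shells slide tangentially under any
  rotation about their centre, so a featureless construct leaves rotations
  unobservable to surface matching. The features are configurable and can
  be disabled.
* The second (femur) bead segment is rendered in small bone plugs — a bead
  free in air loses most of its partial-volume voxels to thresholding.
* `default_phantom()` is the full-size study condition: 40 mm head, 47 mm
  cup, two 9-bead segments (18 beads), streaks on. `compact_phantom()` is
  the simulation-study workhorse: same voxel spacing, materials, bead size
  and noise, but a 20/25.4 mm construct, a single 9-bead segment and a
  ~1.1 M-voxel volume, so a full 32-step protocol with measurement runs in
  well under a minute per seed. Study sizes used by the test-suite and the
  acceptance script (5 and 3 seeds respectively, 9 precision repeats) were
  chosen so a complete run stays in the minutes range on one CPU.
* The displacement protocol mirrors the validation design: 17 single-axis
  translations spanning 0.1–1 mm (6 X, 6 Y, 5 Z) and 15 single-axis
  rotations spanning 0.2–2° about X and 0.17–2° about Y and Z. Only the
  ranges and counts are constrained by the design; magnitudes are evenly
  spaced, and a user-supplied schedule (JSON) is accepted. Rotations are
  about the motion stage's rotation centre, which defaults to the implant
  centre; an offset stage centre is supported and the ground-truth reading
  then includes the induced lever-arm translations.

**What the phantom does not emulate.** No filtered-backprojection physics
(beam hardening, photon starvation, reconstruction kernels), no patient
anatomy or soft tissue, no scanner drift, no table/gantry geometry errors.
Streaks are a geometric surrogate, not a physical scatter model. Passing
the synthetic studies therefore demonstrates the *algorithmic* fidelity of
the chain — segmentation through decomposition — under realistic voxel
geometry, noise and partial-volume conditions; it does not certify
performance on scanner data, which the physical-phantom study design (which
this package reproduces end-to-end) exists to establish.

## Validation statistics

* Precision = 1.96 × sample SD (n−1) of double-measurement readings, per
  axis; the mean signed error is reported separately. Whether to take the
  SD about zero or about the mean is a genuine convention choice; the
  standard sample SD about the mean is used.
* Accuracy = 1.96 × RMS of (measured − imposed), per axis. In a study, each
  axis's errors are collected across *all* analysed steps of the protocol
  (off-axis readings have non-zero ground truth only through lever-arm
  coupling, which the truth computation includes exactly).
* Bland–Altman: x = (imposed + measured)/2, y = measured − imposed, bias
  ± 1.96 SD limits of agreement.
* Observer reproducibility: F = ratio of the two observers' mean squared
  errors about zero (no mean is estimated — the null is zero error), larger
  over smaller, two-sided p from the F distribution with (n₁, n₂) degrees
  of freedom ordered to match; identical observers give F = 1, p = 1.
* Normality: Shapiro–Wilk via scipy (3 ≤ n ≤ 5000).
* Double-measurement errors are each repeat's measurement against the
  single reference scan, not consecutive-pair differences. Repeats include
  a small random rigid repositioning of the whole phantom
  (SD 0.2 mm / 0.2°), emulating removal and replacement in the gantry.
* Steps whose QC flags fire are excluded from study tables and listed by
  label, so a failed scan is bookkept, not averaged in.

## Known limitations

* Precision of the *rotation* axes on the compact phantom is ~0.4–1°,
  noticeably worse than its translation precision (≤ 0.1 mm). Two scale
  effects drive this: the reduced construct halves the angular lever arm,
  and the repositioning roll about the implant's symmetry axis is only
  weakly observable from the surface (the lugs are small). Accuracy studies
  (no repositioning) do not see this term.
* Oblique/rotated CT volumes are rejected, not resampled; a NIfTI
  conversion with axis-aligned geometry is assumed upstream.
* The head/cup split at the glued interface is ambiguous at the voxel
  level in any method — the interface is invisible in CT. The split is kept
  consistent between scans by the robust centre fit, which is what the
  downstream registration actually needs.
* `fit_sphere_centre` (reference point, marker gating) is exact only for a
  single sphere; on a full implant mesh it is biased by the rim but
  reproducibly so.
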