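"""Digital bead-and-implant phantom: CT-like volumes with known rigid motion.

The phantom emulates a hip-resurfacing migration rig: a monobloc ceramic
head cap glued inside a ceramic cup (two concentric hemispherical shells),
surrounded by a low-contrast bone proxy shell carrying ~1 mm radiopaque
marker beads.  Migration is simulated the way a motion stage does it: the
marker segment (beads + bone proxy) is moved in continuous space around the
implant construct, which stays fixed in the world frame, and the scene is
voxelised afterwards.

Voxelisation computes, for every voxel, the occupancy fraction of each solid
by supersampled point-in-solid tests, so grey values carry genuine
partial-volume information:

    grey = background + sum_solids (intensity_solid - background) * occupancy

Solids are accumulated in priority order (beads, implant, bone) so that a
bead embedded in bone reports the bead's intensity, not the sum.  Additive
Gaussian noise (seeded) and an optional streak-artefact model (bright/dark
rays of exponentially decaying amplitude radiating from the implant surface)
complete the image.  Identical spec + seed gives a bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .kinematics import MigrationResult, RigidTransform, recompose
from .volume_io import VoxelVolume

__all__ = [
    "PhantomSpec",
    "MotionStep",
    "StreakParams",
    "default_phantom",
    "compact_phantom",
    "default_protocol",
    "render",
    "render_pair",
]


# --------------------------------------------------------------------------
# solids


@dataclass(frozen=True)
class _Sphere:
    centre: np.ndarray
    radius: float
    intensity: float

    def transformed(self, t: RigidTransform) -> "_Sphere":
        return _Sphere(t.apply(self.centre), self.radius, self.intensity)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.centre - self.radius, self.centre + self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.centre
        return np.einsum("...i,...i->...", d, d) <= self.radius**2

    def classify(self, points: np.ndarray, margin: float):
        """(definitely inside, boundary) masks for voxel centres."""
        d = points - self.centre
        r = np.sqrt(np.einsum("...i,...i->...", d, d))
        inside = r <= self.radius - margin
        outside = r >= self.radius + margin
        return inside, ~(inside | outside)


@dataclass(frozen=True)
class _Cylinder:
    """Finite cylinder: ``centre`` at the midpoint, ``axis`` unit vector."""

    centre: np.ndarray
    axis: np.ndarray
    radius: float
    half_length: float
    intensity: float

    def transformed(self, t: RigidTransform) -> "_Cylinder":
        return _Cylinder(t.apply(self.centre), t.rotation @ self.axis,
                         self.radius, self.half_length, self.intensity)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        reach = np.sqrt(self.radius**2 + self.half_length**2)
        return self.centre - reach, self.centre + reach

    def _coords(self, points: np.ndarray):
        d = points - self.centre
        axial = np.einsum("...i,i->...", d, self.axis)
        radial2 = np.einsum("...i,...i->...", d, d) - axial**2
        return axial, np.sqrt(np.maximum(radial2, 0.0))

    def contains(self, points: np.ndarray) -> np.ndarray:
        axial, radial = self._coords(points)
        return (np.abs(axial) <= self.half_length) & (radial <= self.radius)

    def classify(self, points: np.ndarray, margin: float):
        axial, radial = self._coords(points)
        inside = (np.abs(axial) <= self.half_length - margin) & \
                 (radial <= self.radius - margin)
        outside = (np.abs(axial) >= self.half_length + margin) | \
                  (radial >= self.radius + margin)
        return inside, ~(inside | outside)


@dataclass(frozen=True)
class _ShellCap:
    """Spherical shell between two radii, optionally cut to the half-space
    ``axis . (p - centre) >= 0`` (a hemispherical cap)."""

    centre: np.ndarray
    r_inner: float
    r_outer: float
    intensity: float
    axis: np.ndarray | None = None  # None -> full shell

    def transformed(self, t: RigidTransform) -> "_ShellCap":
        axis = None if self.axis is None else t.rotation @ self.axis
        return _ShellCap(t.apply(self.centre), self.r_inner, self.r_outer,
                         self.intensity, axis)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.centre - self.r_outer, self.centre + self.r_outer

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.centre
        r2 = np.einsum("...i,...i->...", d, d)
        ok = (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)
        if self.axis is not None:
            ok &= np.einsum("...i,i->...", d, self.axis) >= 0
        return ok

    def classify(self, points: np.ndarray, margin: float):
        d = points - self.centre
        r = np.sqrt(np.einsum("...i,...i->...", d, d))
        inside = (r >= self.r_inner + margin) & (r <= self.r_outer - margin)
        outside = (r <= self.r_inner - margin) | (r >= self.r_outer + margin)
        if self.axis is not None:
            axial = np.einsum("...i,i->...", d, self.axis)
            inside &= axial >= margin
            outside |= axial <= -margin
        return inside, ~(inside | outside)


# --------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class StreakParams:
    """Streak-artefact model: rays of exponentially decaying amplitude
    emanating from random points on the implant's outer surface.

    The ray geometry is drawn from ``seed`` (independent of the image-noise
    seed) so repeated renders with different noise share identical
    noise-free content.
    """

    count: int = 24
    amplitude: float = 1500.0  # HU at the ray origin (sign randomised per ray)
    decay_mm: float = 4.0
    seed: int = 20230211


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and acquisition parameters of the digital phantom.

    Bead positions are in the segment-local frame, which coincides with the
    world frame at zero displacement; the implant construct is centred on
    the world origin.  ``marker_beads`` belong to the moving marker segment,
    ``static_beads`` to the second rigid segment fixed with the implant.
    """

    marker_beads: np.ndarray
    static_beads: np.ndarray
    bead_diameter: float = 1.0          # mm
    bead_intensity: float = 3071.0      # HU, 12-bit ceiling (tantalum)
    head_outer_radius: float = 20.0     # mm (40 mm resurfacing head)
    head_thickness: float = 4.0         # mm
    cup_outer_radius: float = 23.5      # mm (47 mm cup)
    cup_thickness: float = 3.5          # mm; cup inner = head outer (glued)
    implant_axis: tuple = (0.0, 0.0, 1.0)
    implant_intensity: float = 3000.0   # HU (ceramic)
    # contoured features breaking the shells' spherical symmetry: a short
    # femoral stem on the head and rim lugs at asymmetric azimuths on the
    # cup.  Surface matching needs them -- rotations slide a pure sphere
    # tangentially -- just as the physical method matches contoured rims.
    head_stem_radius: float = 3.0       # mm; 0 disables
    head_stem_length: float = 10.0      # mm
    cup_lug_radius: float = 2.5         # mm; 0 disables
    cup_lug_azimuths_deg: tuple = (0.0, 100.0, 215.0)
    bone_inner_radius: float = 26.0     # mm
    bone_outer_radius: float = 30.0     # mm
    bone_intensity: float = 700.0       # HU (bone proxy)
    background_intensity: float = -1000.0  # HU (air)
    voxel_spacing: tuple = (0.34, 0.34, 0.6)  # mm
    volume_shape: tuple = (296, 296, 116)
    noise_sd: float = 10.0              # HU
    streaks: StreakParams | None = None
    supersampling: int = 5
    seed: int = 0
    stage_centre: tuple = (0.0, 0.0, 0.0)  # motion-stage rotation centre (mm)

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_beads",
                           np.asarray(self.marker_beads, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "static_beads",
                           np.asarray(self.static_beads, dtype=float).reshape(-1, 3))
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")

    @property
    def bead_positions(self) -> np.ndarray:
        """All bead positions, marker segment first."""
        return np.vstack([self.marker_beads, self.static_beads])

    @property
    def bead_count(self) -> int:
        return len(self.marker_beads) + len(self.static_beads)

    @property
    def cup_inner_radius(self) -> float:
        return self.cup_outer_radius - self.cup_thickness

    @property
    def head_inner_radius(self) -> float:
        return self.head_outer_radius - self.head_thickness

    @property
    def origin(self) -> np.ndarray:
        """World origin placing the implant centre at the volume centre."""
        shape = np.asarray(self.volume_shape, dtype=float)
        spacing = np.asarray(self.voxel_spacing, dtype=float)
        return -(shape - 1) * spacing / 2.0

    def segmentation_threshold(self) -> float:
        """Default HU threshold: midway between bone proxy and implant."""
        return 0.5 * (self.bone_intensity + self.implant_intensity)


@dataclass(frozen=True)
class MotionStep:
    """One protocol step: a labelled ground-truth 6-DoF displacement of the
    marker segment relative to the implant segment."""

    label: str
    imposed: MigrationResult

    @property
    def is_single_axis(self) -> bool:
        return int(np.count_nonzero(self.imposed.as_array())) == 1


# --------------------------------------------------------------------------
# defaults


def _spread_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _marker_bead_positions(radius: float, n: int = 9) -> np.ndarray:
    return radius * _spread_directions(n)


def _static_bead_positions(radius: float, z_max: float, n: int = 9) -> np.ndarray:
    """Second-segment beads at |p| = radius with |z| clamped to z_max so the
    volume can stay short along the scan axis."""
    pts = radius * _spread_directions(n)
    for p in pts:
        if abs(p[2]) > z_max:
            p[2] = np.sign(p[2]) * z_max
            xy = np.sqrt(radius**2 - z_max**2) / max(np.hypot(p[0], p[1]), 1e-12)
            p[0] *= xy
            p[1] *= xy
    return pts


def default_phantom(**overrides) -> PhantomSpec:
    """Full-size phantom: 40 mm head in a 47 mm cup, two 9-bead segments
    (18 beads total), 0.34 x 0.34 x 0.6 mm voxels, 10 HU noise and a mild
    streak model.  Keyword overrides replace any spec field."""
    spec = PhantomSpec(
        marker_beads=_marker_bead_positions(28.0),
        static_beads=_static_bead_positions(43.0, z_max=20.0),
        streaks=StreakParams(),
    )
    return replace(spec, **overrides) if overrides else spec


def compact_phantom(**overrides) -> PhantomSpec:
    """Reduced phantom for simulation studies: same voxel spacing, materials
    and bead size as :func:`default_phantom`, but a 20/25.4 mm head/cup
    construct and a single 9-bead marker segment, so a full displacement
    protocol renders in seconds instead of minutes."""
    spec = PhantomSpec(
        marker_beads=_marker_bead_positions(15.5),
        static_beads=np.empty((0, 3)),
        head_outer_radius=10.0,
        head_thickness=2.5,
        cup_outer_radius=12.7,
        cup_thickness=2.7,
        head_stem_radius=2.5,
        head_stem_length=7.0,
        cup_lug_radius=1.5,
        bone_inner_radius=14.0,
        bone_outer_radius=17.0,
        volume_shape=(126, 126, 72),
        supersampling=3,
        streaks=None,
    )
    return replace(spec, **overrides) if overrides else spec


def _single_axis_step(label: str, axis: str, value: float,
                      rotation_centre) -> MotionStep:
    params = dict(tx=0.0, ty=0.0, tz=0.0, rx=0.0, ry=0.0, rz=0.0)
    params[axis] = value
    return MotionStep(label, MigrationResult(**params,
                                             reference_point=rotation_centre))


def default_protocol(kind: str, rotation_centre=(0.0, 0.0, 0.0)) -> list[MotionStep]:
    """The displacement schedule of the validation study.

    ``kind='translations'``: 17 single-axis steps spanning 0.1-1 mm
    (6 along X, 6 along Y, 5 along Z).  ``kind='rotations'``: 15 single-axis
    steps, 0.2-2 degrees about X and 0.17-2 degrees about Y and Z (5 each).
    Only the ranges and counts are constrained; magnitudes are evenly spaced
    within each axis.  Rotations are about ``rotation_centre`` (the motion
    stage's centre of rotation).
    """
    centre = np.asarray(rotation_centre, dtype=float)
    steps: list[MotionStep] = []
    if kind == "translations":
        for axis, n in (("tx", 6), ("ty", 6), ("tz", 5)):
            for v in np.linspace(0.1, 1.0, n):
                steps.append(_single_axis_step(
                    f"{axis}_{v:.3f}mm", axis, float(v), centre))
    elif kind == "rotations":
        for axis, lo in (("rx", 0.2), ("ry", 0.17), ("rz", 0.17)):
            for v in np.linspace(lo, 2.0, 5):
                steps.append(_single_axis_step(
                    f"{axis}_{v:.3f}deg", axis, float(v), centre))
    else:
        raise ValueError(f"kind must be 'translations' or 'rotations', got {kind!r}")
    return steps


# --------------------------------------------------------------------------
# rendering


def _scene_solids(spec: PhantomSpec,
                  displacement: RigidTransform | None,
                  global_pose: RigidTransform | None) -> list:
    """Solids in accumulation priority order (beads, implant, bone).

    ``displacement`` moves the marker segment (marker beads + bone proxy);
    ``global_pose`` repositions the whole phantom (gantry placement).
    """
    disp = displacement or RigidTransform.identity()
    pose = global_pose or RigidTransform.identity()
    centre = np.zeros(3)
    axis = np.asarray(spec.implant_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r = spec.bead_diameter / 2.0

    solids: list = []
    for p in spec.marker_beads:
        solids.append(_Sphere(disp.apply(p), r, spec.bead_intensity))
    for p in spec.static_beads:
        solids.append(_Sphere(np.asarray(p, dtype=float), r, spec.bead_intensity))
    solids.append(_ShellCap(centre, spec.head_inner_radius, spec.head_outer_radius,
                            spec.implant_intensity, axis))
    solids.append(_ShellCap(centre, spec.cup_inner_radius, spec.cup_outer_radius,
                            spec.implant_intensity, axis))
    if spec.head_stem_radius > 0 and spec.head_stem_length > 0:
        # spans from the dome apex down into the bone so it stays one
        # connected component with the head shell
        span = spec.head_outer_radius + spec.head_stem_length
        solids.append(_Cylinder(
            centre + axis * (spec.head_outer_radius - spec.head_stem_length) / 2.0,
            axis, spec.head_stem_radius, span / 2.0, spec.implant_intensity))
    if spec.cup_lug_radius > 0:
        # an orthonormal basis in the rim plane
        e1 = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(axis, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        rim = 0.5 * (spec.cup_inner_radius + spec.cup_outer_radius)
        for az in spec.cup_lug_azimuths_deg:
            a = np.deg2rad(az)
            solids.append(_Sphere(centre + rim * (np.cos(a) * e1 + np.sin(a) * e2),
                                  spec.cup_lug_radius, spec.implant_intensity))
    bone = _ShellCap(centre, spec.bone_inner_radius, spec.bone_outer_radius,
                     spec.bone_intensity, None)
    solids.append(bone.transformed(disp))
    # each second-segment bead sits in a small plug of bone, as in the
    # physical set-up (beads are implanted into bone, never free in air)
    for p in spec.static_beads:
        solids.append(_Sphere(np.asarray(p, dtype=float), 2.0,
                              spec.bone_intensity))
    if not pose.is_identity():
        solids = [s.transformed(pose) for s in solids]
    return solids


_CHUNK = 16384  # boundary voxels supersampled per chunk (memory bound)


def _solid_occupancy(solid, spec: PhantomSpec, lo_idx, hi_idx) -> np.ndarray:
    """Occupancy fractions of ``solid`` over the index box [lo_idx, hi_idx)."""
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    origin = spec.origin
    ss = spec.supersampling
    margin = 0.5 * float(np.linalg.norm(spacing))

    grids = [origin[a] + spacing[a] * np.arange(lo_idx[a], hi_idx[a])
             for a in range(3)]
    centres = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1)
    inside, boundary = solid.classify(centres, margin)
    occ = inside.astype(np.float32)
    if ss == 1 or not boundary.any():
        if ss == 1 and boundary.any():
            occ[boundary] = solid.contains(centres[boundary]).astype(np.float32)
        return occ

    # sub-voxel sample offsets: ss^3 points per voxel, cell-centred
    offs1d = [((np.arange(ss) + 0.5) / ss - 0.5) * spacing[a] for a in range(3)]
    offsets = np.stack(np.meshgrid(*offs1d, indexing="ij"), axis=-1).reshape(-1, 3)
    bpts = centres[boundary]
    fracs = np.empty(len(bpts), dtype=np.float32)
    for s in range(0, len(bpts), _CHUNK):
        chunk = bpts[s:s + _CHUNK]
        hits = solid.contains(chunk[:, None, :] + offsets[None, :, :])
        fracs[s:s + _CHUNK] = hits.mean(axis=1, dtype=np.float64)
    occ[boundary] = fracs
    return occ


def _apply_streaks(values: np.ndarray, spec: PhantomSpec,
                   global_pose: RigidTransform | None) -> None:
    sp = spec.streaks
    if sp is None or sp.count == 0:
        return
    pose = global_pose or RigidTransform.identity()
    rng = np.random.default_rng(sp.seed)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    origin = spec.origin
    step = float(spacing.min()) / 2.0
    n_steps = max(2, int(3.0 * sp.decay_mm / step))
    # rays pass through the surface point in both directions
    s = np.arange(-n_steps, n_steps) * step
    amp_profile = sp.amplitude * np.exp(-np.abs(s) / sp.decay_mm)
    for _ in range(sp.count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        start = pose.apply(spec.cup_outer_radius * u)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pts = start + s[:, None] * v
        idx = np.rint((pts - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(values.shape)), axis=1)
        # one deposit per voxel (the strongest sample), not one per sample
        order = np.argsort(-amp_profile[ok])
        uniq, first = np.unique(idx[ok][order], axis=0, return_index=True)
        values[tuple(uniq.T)] += sign * amp_profile[ok][order][first]


def render(spec: PhantomSpec,
           displacement: RigidTransform | None = None,
           global_pose: RigidTransform | None = None,
           noise_seed=None) -> VoxelVolume:
    """Voxelise the phantom with the marker segment displaced by
    ``displacement`` (implant fixed in the world frame).

    ``global_pose`` additionally repositions the whole phantom, emulating
    removal and replacement in the gantry between scans.  ``noise_seed``
    overrides ``spec.seed`` for the Gaussian noise realisation.
    """
    shape = tuple(int(n) for n in spec.volume_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    origin = spec.origin
    upper = origin + (np.asarray(shape) - 1) * spacing

    values = np.full(shape, spec.background_intensity, dtype=np.float64)
    occupied = np.zeros(shape, dtype=np.float32)

    for solid in _scene_solids(spec, displacement, global_pose):
        lo_mm, hi_mm = solid.bounds()
        if np.any(lo_mm < origin - spacing) or np.any(hi_mm > upper + spacing):
            raise ValueError(
                f"solid bounds {lo_mm}..{hi_mm} mm exit the volume "
                f"{origin}..{upper} mm"
            )
        lo = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 2, shape)
        occ = _solid_occupancy(solid, spec, lo, hi)
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        occ_eff = np.clip(occ - occupied[sub], 0.0, 1.0)
        values[sub] += (solid.intensity - spec.background_intensity) * occ_eff
        occupied[sub] += occ_eff

    _apply_streaks(values, spec, global_pose)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
        values += rng.normal(0.0, spec.noise_sd, size=shape)

    return VoxelVolume(values, spacing, origin)


def render_pair(spec: PhantomSpec, step: MotionStep, seed=None):
    """Reference scan (zero displacement) plus target scan at the step's
    imposed displacement, with independent noise realisations.

    Returns ``(reference, target, truth)`` where ``truth`` echoes
    ``step.imposed`` (the marker-segment motion relative to the implant).
    """
    base = spec.seed if seed is None else seed
    displacement = recompose(step.imposed)
    reference = render(spec, None, noise_seed=[base, 0])
    target = render(spec, displacement, noise_seed=[base, 1])
    return reference, target, step.imposed


def protocol_from_json(steps: Sequence[dict]) -> list[MotionStep]:
    """Load a user-supplied schedule: a JSON list of
    ``{label, tx, ty, tz, rx, ry, rz, reference_point}`` objects."""
    out = []
    for d in steps:
        out.append(MotionStep(
            d.get("label", "step"),
            MigrationResult(
                d.get("tx", 0.0), d.get("ty", 0.0), d.get("tz", 0.0),
                d.get("rx", 0.0), d.get("ry", 0.0), d.get("rz", 0.0),
                reference_point=d.get("reference_point", (0.0, 0.0, 0.0)),
            ),
        ))
    return out
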