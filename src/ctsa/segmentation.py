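"""Threshold segmentation of beads and implant from a CT volume.

The pipeline thresholds the volume, labels 26-connected components, sizes
them against the nominal bead volume to separate beads from the implant
construct and debris, splits the glued head/cup construct by fitted radius,
and removes streak artefact (scatter radiating from the implant surface)
with a deterministic grey-level + morphological rule.  Masks keep their
grey values so downstream bead localisation can weight by them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from skimage.measure import marching_cubes

from .volume_io import SurfaceMesh, VoxelVolume

__all__ = [
    "VoxelMask",
    "ClassifiedComponents",
    "SegmentationError",
    "segment_candidates",
    "classify_components",
    "split_implant",
    "remove_artefact",
    "extract_surface",
]


class SegmentationError(RuntimeError):
    pass


@dataclass
class VoxelMask:
    """A connected set of voxels with their grey values (HU) and the source
    volume's geometry, so world coordinates can be recovered."""

    voxel_indices: np.ndarray  # (N, 3) int
    grey_values: np.ndarray    # (N,)
    source_spacing: np.ndarray
    source_origin: np.ndarray
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64).reshape(-1, 3)
        self.grey_values = np.asarray(self.grey_values, dtype=float).reshape(-1)
        self.source_spacing = np.asarray(self.source_spacing, dtype=float).reshape(3)
        self.source_origin = np.asarray(self.source_origin, dtype=float).reshape(3)
        if len(self.voxel_indices) != len(self.grey_values):
            raise ValueError("voxel_indices and grey_values length mismatch")

    def __len__(self) -> int:
        return len(self.voxel_indices)

    @property
    def world_coordinates(self) -> np.ndarray:
        """(N, 3) world mm positions of the voxel centres."""
        return self.voxel_indices * self.source_spacing + self.source_origin

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.source_spacing))

    @property
    def physical_volume(self) -> float:
        """Occupied volume in mm^3 (voxel count x voxel volume)."""
        return len(self) * self.voxel_volume

    def with_flag(self, flag: str) -> "VoxelMask":
        return replace(self, flags=self.flags + (flag,))


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_candidates(volume: VoxelVolume, threshold: float,
                       allow_empty: bool = False) -> list[VoxelMask]:
    """All 26-connected components of voxels >= ``threshold``, largest first."""
    binary = volume.values >= threshold
    if not binary.any():
        if allow_empty:
            return []
        raise SegmentationError(f"no voxel at or above threshold {threshold}")
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    masks = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        local = labels[sl] == lab
        ijk = np.argwhere(local) + [s.start for s in sl]
        masks.append(VoxelMask(
            ijk, volume.values[tuple(ijk.T)], volume.spacing, volume.origin))
    masks.sort(key=len, reverse=True)
    return masks


@dataclass
class ClassifiedComponents:
    beads: list
    implant: VoxelMask | None
    rejected: list
    flags: tuple = ()


def classify_components(masks: list, bead_diameter: float,
                        expected_beads: int | None = None,
                        implant_margin_mm: float = 1.5) -> ClassifiedComponents:
    """Split components into bead-sized ones, the implant construct
    (largest non-bead component) and rejected debris/artefact.

    Bead-sized means physical volume within [0.2x, 3x] the nominal sphere
    volume of ``bead_diameter``.  Bead-sized components closer than
    ``implant_margin_mm`` to the implant are scatter radiating from the
    implant surface, not markers (beads live in bone, clear of the
    implant), and are rejected.  A merged bead+implant component cannot be
    recovered here; passing ``expected_beads`` flags the shortfall so the
    caller never silently proceeds with a mis-sized set.
    """
    if not masks:
        raise SegmentationError("no components to classify")
    nominal = np.pi / 6.0 * bead_diameter**3
    beads, others = [], []
    for m in masks:
        (beads if 0.2 * nominal <= m.physical_volume <= 3.0 * nominal
         else others).append(m)
    flags: list[str] = []
    implant = None
    rejected: list = []
    if others:
        others.sort(key=len, reverse=True)
        implant, rejected = others[0], others[1:]
        if rejected and rejected[0].physical_volume > 0.5 * implant.physical_volume:
            flags.append("ambiguous_implant")
    else:
        flags.append("no_implant_component")
    if implant is not None and beads and implant_margin_mm > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(implant.world_coordinates)
        kept = []
        for m in beads:
            if tree.query(m.world_coordinates)[0].min() < implant_margin_mm:
                rejected.append(m.with_flag("implant_adjacent_artefact"))
            else:
                kept.append(m)
        beads = kept
    if not beads:
        flags.append("no_bead_sized_components")
    if expected_beads is not None and len(beads) != expected_beads:
        flags.append(f"bead_count_{len(beads)}_expected_{expected_beads}")
    return ClassifiedComponents(beads, implant, rejected, tuple(flags))


def _fit_common_centre(points: np.ndarray, mid_radii,
                       f_scale: float) -> tuple[np.ndarray, float]:
    """Centre of concentric spherical shells best explaining the points;
    returns (centre, median |residual to nearest mid-surface|).

    Each voxel is scored against the nearest shell *mid-surface* radius.
    Mid-surfaces matter: scoring against the outer radii lets an axial
    shift snap mid-shell voxels onto the wrong surface, giving spurious
    minima, whereas a thick shell is symmetric about its mid-surface so the
    true centre is the optimum.  A closed-form algebraic sphere fit seeds a
    robust (Cauchy, ``f_scale`` = half shell thickness) refinement, so
    off-model features (stem, lugs) cannot drag the centre.
    """
    mids = np.asarray(mid_radii, dtype=float)
    # algebraic init: |p - c|^2 = r^2  =>  linear in (c, r^2 - |c|^2)
    a = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.einsum("ij,ij->i", points, points)
    init = np.linalg.lstsq(a, b, rcond=None)[0][:3]

    def resid(c):
        r = np.linalg.norm(points - c, axis=1)
        return np.min(np.abs(r[:, None] - mids[None, :]), axis=1)

    sol = optimize.least_squares(resid, init, loss="cauchy",
                                 f_scale=f_scale, method="trf")
    return sol.x, float(np.median(resid(sol.x)))


def split_implant(implant: VoxelMask, head_radius: float, cup_radius: float,
                  head_thickness: float | None = None,
                  cup_thickness: float | None = None,
                  fit_tolerance: float | None = None
                  ) -> tuple[VoxelMask, VoxelMask]:
    """Assign construct voxels to head or cup by radial distance from the
    fitted common centre of the two shells.

    ``head_radius`` / ``cup_radius`` are the outer radii (mm); thicknesses
    default to 25% of each radius.  The decision boundary is the smaller of
    the two outer radii (the glued head/cup interface); swapping the radii
    in the config swaps the two outputs symmetrically.  Raises on fit
    failure (residuals say the mask is not concentric shells).
    """
    if head_thickness is None:
        head_thickness = 0.25 * head_radius
    if cup_thickness is None:
        cup_thickness = 0.25 * cup_radius
    if fit_tolerance is None:
        # legitimate thick shells give a median residual near thickness/4
        fit_tolerance = 0.45 * max(head_thickness, cup_thickness)
    pts = implant.world_coordinates
    centre, med_resid = _fit_common_centre(
        pts, [head_radius - head_thickness / 2, cup_radius - cup_thickness / 2],
        f_scale=0.5 * max(head_thickness, cup_thickness))
    if med_resid > fit_tolerance:
        raise SegmentationError(
            f"spherical-shell fit failed (median residual {med_resid:.2f} mm)")
    r = np.linalg.norm(pts - centre, axis=1)
    boundary = min(head_radius, cup_radius) + 0.25 * float(implant.source_spacing.min())
    inner = r <= boundary
    head_sel = inner if head_radius <= cup_radius else ~inner

    def subset(sel):
        return VoxelMask(implant.voxel_indices[sel], implant.grey_values[sel],
                         implant.source_spacing, implant.source_origin,
                         flags=implant.flags)

    return subset(head_sel), subset(~head_sel)


def remove_artefact(mask: VoxelMask, volume: VoxelVolume,
                    intensity_fraction: float = 0.6) -> VoxelMask:
    """Strip streak artefact from an implant candidate mask.

    Removes voxels dimmer than ``intensity_fraction`` of the mask's median
    grey value, then removes thin protrusions that neither survive a
    6-connected morphological opening nor are solidly attached (at least 9
    of 26 neighbours in the mask): streak rays are voxel-wide chains and
    bumps, while genuine surface staircase voxels sit on the shell body.
    If the rule would delete more than half the mask, the input is returned
    flagged instead.
    """
    if len(mask) == 0:
        raise SegmentationError("empty implant mask")
    bright = mask.grey_values >= intensity_fraction * np.median(mask.grey_values)

    lo = mask.voxel_indices.min(axis=0) - 1
    shape = mask.voxel_indices.max(axis=0) - lo + 3
    binary = np.zeros(shape, dtype=bool)
    local = mask.voxel_indices - lo
    binary[tuple(local[bright].T)] = True
    opened = ndimage.binary_opening(
        binary, structure=ndimage.generate_binary_structure(3, 1))
    neighbours = ndimage.convolve(binary.astype(np.int8),
                                  np.ones((3, 3, 3), np.int8),
                                  mode="constant") - 1
    solid = opened | (neighbours >= 9)
    keep = bright & solid[tuple(local.T)]

    if keep.sum() < 0.5 * len(mask):
        return mask.with_flag("artefact_removal_exceeds_half")
    if keep.all():
        return mask
    return VoxelMask(mask.voxel_indices[keep], mask.grey_values[keep],
                     mask.source_spacing, mask.source_origin, flags=mask.flags)


def apply_exclusion_list(mask: VoxelMask, exclusions) -> VoxelMask:
    """Manual override hook: drop voxels inside (lo_ijk, hi_ijk) index boxes
    (inclusive), mirroring an operator's artefact call, with an audit flag."""
    keep = np.ones(len(mask), dtype=bool)
    for lo, hi in exclusions:
        lo = np.asarray(lo, dtype=np.int64)
        hi = np.asarray(hi, dtype=np.int64)
        inside = np.all((mask.voxel_indices >= lo) & (mask.voxel_indices <= hi), axis=1)
        keep &= ~inside
    if keep.all():
        return mask
    return VoxelMask(mask.voxel_indices[keep], mask.grey_values[keep],
                     mask.source_spacing, mask.source_origin,
                     flags=mask.flags + ("manual_exclusion",))


def extract_surface(mask: VoxelMask, volume: VoxelVolume, iso: float) -> SurfaceMesh:
    """Marching-cubes iso-surface of the masked region, vertices in world mm.

    Around the mask the true grey field is kept, so the surface sits at the
    genuine sub-voxel iso crossing rather than at a voxel boundary; only
    bright voxels that are *not* part of the mask (the mating implant or
    other removed structure) are clamped below ``iso``, closing the surface
    with a sharp cut there.
    """
    if len(mask) == 0:
        raise SegmentationError("empty mask")
    if iso >= mask.grey_values.max():
        raise SegmentationError(
            f"iso level {iso} at or above mask maximum {mask.grey_values.max()}")
    lo = np.maximum(mask.voxel_indices.min(axis=0) - 2, 0)
    hi = np.minimum(mask.voxel_indices.max(axis=0) + 3,
                    np.asarray(volume.shape))
    fill = iso - max(1.0, 0.1 * abs(iso))
    sub = volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
    local = mask.voxel_indices - lo
    in_mask = np.zeros(sub.shape, dtype=bool)
    in_mask[tuple(local.T)] = True
    sub[~in_mask & (sub >= fill)] = fill
    sub[tuple(local.T)] = np.maximum(mask.grey_values, fill)
    # guarantee closure at the crop border
    for axis in range(3):
        for edge in (0, -1):
            face = [slice(None)] * 3
            face[axis] = edge
            sub[tuple(face)] = fill
    verts, faces, _, _ = marching_cubes(sub, level=iso,
                                        spacing=tuple(mask.source_spacing))
    verts = verts + mask.source_origin + lo * mask.source_spacing
    good = ~((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
             | (faces[:, 0] == faces[:, 2]))
    return SurfaceMesh(verts, faces[good])
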