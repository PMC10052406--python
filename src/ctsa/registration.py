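"""Implant surface matching (coarse alignment + ICP), paired-point rigid
fitting, and the end-to-end migration measurement pipeline.

Migration between a reference and a target CT scan is measured in the
implant-anchored frame: the target implant surface is registered onto the
reference implant surface (coarse principal-axes alignment followed by
point-to-point iterative closest point), the same transform repositions the
target bead centres, and the residual rigid motion between the paired bead
sets is the bone-marker movement relative to the implant.  Its inverse --
the implant's movement relative to the fixed bone markers, the clinical
convention -- is decomposed into three translations of the implant centre
(mm) and three extrinsic X->Y->Z Euler rotations (degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from . import segmentation as seg
from .bead_analysis import (BeadSet, beads_from_masks, condition_number,
                            pair_beads)
from .kinematics import MigrationResult, RigidTransform, decompose, invert
from .volume_io import SurfaceMesh, VoxelVolume

__all__ = [
    "ICPResult",
    "MeasureConfig",
    "MigrationReport",
    "coarse_align",
    "icp",
    "fit_rigid_paired",
    "fit_sphere_centre",
    "measure_migration",
]


# --------------------------------------------------------------------------
# rigid fitting


def fit_rigid_paired(ref_pts: np.ndarray, tgt_pts: np.ndarray,
                     weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares optimal proper rigid transform mapping ``ref_pts`` onto
    ``tgt_pts`` (closed-form weighted SVD solution, reflection-corrected)."""
    ref = np.asarray(ref_pts, dtype=float).reshape(-1, 3)
    tgt = np.asarray(tgt_pts, dtype=float).reshape(-1, 3)
    if ref.shape != tgt.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(ref)
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if len(w) != n or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cr = w @ ref
    ct = w @ tgt
    a = ref - cr
    b = tgt - ct
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError("reference points are collinear; rotation is undetermined")
    h = a.T @ (w[:, None] * b)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, ct - rot @ cr)


def fit_sphere_centre(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere-centre fit (radius discarded).

    Exact for points on one sphere; for a mixture of concentric surfaces
    (an implant mesh of nested shells plus rim) it lands within a fraction
    of a millimetre of the common centre, which is all the reference-point
    and marker-gating uses require -- and, crucially, it is closed-form and
    therefore reproducible between scans.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


# --------------------------------------------------------------------------
# coarse alignment


def coarse_align(moving: SurfaceMesh, fixed: SurfaceMesh
                 ) -> tuple[RigidTransform, tuple]:
    """Deterministic starting transform mapping ``moving`` roughly onto
    ``fixed``: centroids coincide and principal axes align, with axis signs
    disambiguated by the third central moment (skewness) along each axis.

    Degenerate cases -- near-equal principal-axis eigenvalues (rotational
    symmetry) or near-zero skewness -- cannot be aligned unambiguously;
    they fall back to centroid-only translation and are flagged, which is
    the correct start when the surfaces have barely moved.
    """

    def frame(mesh):
        pts = mesh.vertices
        c = pts.mean(axis=0)
        d = pts - c
        evals, evecs = np.linalg.eigh(d.T @ d / len(d))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        skews = np.array([np.mean((d @ evecs[:, k]) ** 3) for k in range(3)])
        return c, evals, evecs, skews

    c_m, ev_m, ax_m, sk_m = frame(moving)
    c_f, ev_f, ax_f, sk_f = frame(fixed)

    scale_m = np.mean(ev_m)
    degenerate = (
        ev_m[0] - ev_m[1] < 0.05 * scale_m
        or ev_m[1] - ev_m[2] < 0.05 * scale_m
        or ev_f[0] - ev_f[1] < 0.05 * np.mean(ev_f)
        or ev_f[1] - ev_f[2] < 0.05 * np.mean(ev_f)
    )
    skew_floor = 0.05 * scale_m ** 1.5
    if not degenerate and (np.any(np.abs(sk_m[:2]) < skew_floor)
                           or np.any(np.abs(sk_f[:2]) < skew_floor)):
        degenerate = True

    if degenerate:
        return (RigidTransform(np.eye(3), c_f - c_m),
                ("coarse_align_degenerate_axes",))

    for k in range(2):  # fix signs of the two strongest axes by skewness
        if np.sign(sk_m[k]) != np.sign(sk_f[k]):
            ax_m[:, k] = -ax_m[:, k]
    # right-handedness pins the third axis
    ax_m[:, 2] = np.cross(ax_m[:, 0], ax_m[:, 1])
    ax_f[:, 2] = np.cross(ax_f[:, 0], ax_f[:, 1])
    rot = ax_f @ ax_m.T
    return RigidTransform(rot, c_f - rot @ c_m), ()


# --------------------------------------------------------------------------
# iterative closest point


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each candidate triangle (Ericson's region method,
    vectorised): ``points`` (N, 3), ``tri`` (N, K, 3, 3) -> (N, K, 3)."""
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab, ac = b - a, c - a
    ap, bp, cp = p - a, p - b, p - c
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    def safe(x):
        return np.where(x != 0, x, 1.0)

    denom = safe(va + vb + vc)
    res = a + (vb / denom)[..., None] * ab + (vc / denom)[..., None] * ac
    m = (vb <= 0) & (d2 > 0) & (d6 <= 0)  # edge AC
    t = np.clip(d2 / safe(d2 - d6), 0, 1)
    res = np.where(m[..., None], a + t[..., None] * ac, res)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    t = np.clip(d1 / safe(d1 - d3), 0, 1)
    res = np.where(m[..., None], a + t[..., None] * ab, res)
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    t = np.clip((d4 - d3) / safe((d4 - d3) + (d5 - d6)), 0, 1)
    res = np.where(m[..., None], b + t[..., None] * (c - b), res)
    res = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, res)
    res = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, res)
    res = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, res)
    return res


class _SurfaceLookup:
    """Nearest point on a triangulated surface, via a k-d tree over face
    centroids and exact point-triangle projection on the K best candidates."""

    def __init__(self, mesh: SurfaceMesh, k: int = 6):
        self.triangles = mesh.vertices[mesh.faces]
        self.tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(mesh.faces))

    def query(self, points: np.ndarray):
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        proj = _closest_on_triangles(points, self.triangles[idx])
        d2 = np.einsum("nkj,nkj->nk", proj - points[:, None, :],
                       proj - points[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return np.sqrt(d2[rows, best]), proj[rows, best]


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    cost_trace: list


def icp(moving: SurfaceMesh, fixed: SurfaceMesh,
        init: RigidTransform | None = None,
        tol: float = 1e-4, max_iter: int = 100,
        sample: int | None = None,
        correspondence: str = "surface",
        trim: float = 0.0) -> ICPResult:
    """Point-to-point ICP aligning ``moving`` vertices onto the ``fixed``
    surface, with a closed-form rigid update per iteration.

    Correspondences are the exact closest points on the fixed triangulated
    surface (``correspondence='surface'``, the default) or the nearest
    fixed vertices (``'vertex'``).  Surface correspondences matter on CT
    meshes: nearest-vertex matching locks onto the slice-spacing vertex
    rings of smooth surfaces and aliases small rotations into ring-to-ring
    false minima.  The cost trace records the RMS closest-point distance
    under each iterate's own correspondences, which is non-increasing for
    this update.  ``sample`` caps the number of moving vertices used
    (deterministic even subsample); the default uses all of them.  Stops
    when the RMS change drops below ``tol`` (mm) or at ``max_iter``, in
    which case ``converged`` is False and the best transform so far is
    still returned.  ``trim`` drops that worst fraction of correspondences
    from each update (useful for artefact-clipped meshes); it is off by
    default and the cost trace then tracks the trimmed RMS.
    """
    if not 0.0 <= trim < 1.0:
        raise ValueError("trim must be in [0, 1)")
    pts = moving.vertices
    if sample is not None and len(pts) > sample:
        pts = pts[np.linspace(0, len(pts) - 1, sample).astype(int)]
    if correspondence == "surface":
        lookup = _SurfaceLookup(fixed).query
    elif correspondence == "vertex":
        tree = cKDTree(fixed.vertices)

        def lookup(q):
            d, nn = tree.query(q)
            return d, fixed.vertices[nn]
    else:
        raise ValueError("correspondence must be 'surface' or 'vertex'")

    t = init or RigidTransform.identity()
    trace: list[float] = []
    converged = False
    src = pts
    for _ in range(max_iter):
        dists, targets = lookup(t.apply(pts))
        if trim > 0.0:
            keep = np.argsort(dists)[: max(3, int(np.ceil(len(dists) * (1 - trim))))]
            dists, targets, src = dists[keep], targets[keep], pts[keep]
        rms = float(np.sqrt(np.mean(dists**2)))
        trace.append(rms)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < tol:
            converged = True
            break
        t = fit_rigid_paired(src, targets)
    return ICPResult(t, trace[-1], len(trace), converged, trace)


# --------------------------------------------------------------------------
# end-to-end measurement


@dataclass(frozen=True)
class MeasureConfig:
    """Settings for :func:`measure_migration`.

    ``reference_point`` is the point whose displacement is reported (the
    implant centre by convention); left as None it is taken from the sphere
    fitted to the analysed implant surface of the reference scan.
    ``analysed`` picks which implant's migration is measured ('head' or
    'cup'); the mating implant is discarded after the construct is split
    using ``head_radius`` / ``cup_radius`` (outer radii, mm).
    """

    threshold: float = 1850.0
    bead_diameter: float = 1.0
    weight_reference: float = 700.0      # HU floor for centroid weights
    analysed: str = "cup"
    head_radius: float = 20.0
    cup_radius: float = 23.5
    head_thickness: float = 4.0
    cup_thickness: float = 3.5
    artefact_fraction: float = 0.6
    icp_tol: float = 1e-4
    icp_max_iter: int = 100
    icp_sample: int | None = 4000
    icp_trim: float = 0.0
    reference_point: tuple | None = None
    initial_transform: RigidTransform | None = None  # operator-supplied start
    marker_max_radius: float | None = None  # gate to the analysed bead segment
    expected_beads: int | None = None
    weighted_bead_fit: bool = False
    manual_exclusions: tuple = ()

    @classmethod
    def for_phantom(cls, spec, analysed: str = "cup", **overrides) -> "MeasureConfig":
        """Defaults tied to a :class:`~ctsa.synthetic_phantom.PhantomSpec`."""
        n_marker = len(spec.marker_beads)
        n_static = len(spec.static_beads)
        gate = None
        if n_static:
            # analysed segment sits inside the bone shell; the second
            # segment is placed well outside it
            gate = 0.5 * (spec.bone_outer_radius
                          + float(np.linalg.norm(spec.static_beads, axis=1).min()))
        cfg = cls(
            threshold=spec.segmentation_threshold(),
            bead_diameter=spec.bead_diameter,
            weight_reference=spec.bone_intensity,
            analysed=analysed,
            head_radius=spec.head_outer_radius,
            cup_radius=spec.cup_outer_radius,
            head_thickness=spec.head_thickness,
            cup_thickness=spec.cup_thickness,
            marker_max_radius=gate,
            expected_beads=n_marker + n_static,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class QCReport:
    condition_number_reference: float
    condition_number_target: float
    icp_rms: float
    icp_converged: bool
    icp_iterations: int
    bead_pairs: int
    beads_excluded_reference: int
    beads_excluded_target: int
    flags: tuple = ()

    @property
    def acceptable(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        return {
            "condition_number_reference": self.condition_number_reference,
            "condition_number_target": self.condition_number_target,
            "icp_rms_mm": self.icp_rms,
            "icp_converged": self.icp_converged,
            "icp_iterations": self.icp_iterations,
            "bead_pairs": self.bead_pairs,
            "beads_excluded_reference": self.beads_excluded_reference,
            "beads_excluded_target": self.beads_excluded_target,
            "flags": list(self.flags),
        }


@dataclass
class MigrationReport:
    result: MigrationResult
    transform: RigidTransform  # implant motion relative to the markers
    qc: QCReport
    pairing: object | None = None  # BeadPairing used for the fit

    def to_dict(self) -> dict:
        return {"result": self.result.to_dict(),
                "transform": self.transform.to_dict(),
                "qc": self.qc.to_dict()}


@dataclass
class _ScanFeatures:
    beads: BeadSet
    mesh: SurfaceMesh
    implant_centre: np.ndarray
    n_excluded_beads: int
    flags: tuple


def _artefact_overlap_exclusion(bead_masks, rejected, spacing) -> tuple[list, int]:
    """Drop beads whose voxels touch a rejected artefact component."""
    if not rejected or not bead_masks:
        return list(bead_masks), 0
    rej = np.vstack([m.world_coordinates for m in rejected])
    tree = cKDTree(rej)
    reach = float(np.linalg.norm(spacing))
    kept = [m for m in bead_masks
            if not (tree.query(m.world_coordinates)[0] <= reach).any()]
    return kept, len(bead_masks) - len(kept)


def _extract_features(volume: VoxelVolume, cfg: MeasureConfig) -> _ScanFeatures:
    flags: list[str] = []
    masks = seg.segment_candidates(volume, cfg.threshold)
    parts = seg.classify_components(masks, cfg.bead_diameter,
                                    expected_beads=cfg.expected_beads)
    flags.extend(parts.flags)
    if parts.implant is None:
        raise seg.SegmentationError("no implant component found")

    implant = seg.remove_artefact(parts.implant, volume, cfg.artefact_fraction)
    flags.extend(f for f in implant.flags if f not in flags)
    if cfg.manual_exclusions:
        implant = seg.apply_exclusion_list(implant, cfg.manual_exclusions)
    head, cup = seg.split_implant(implant, cfg.head_radius, cfg.cup_radius,
                                  cfg.head_thickness, cfg.cup_thickness)
    analysed = head if cfg.analysed == "head" else cup
    if len(analysed) == 0:
        raise seg.SegmentationError(f"analysed implant '{cfg.analysed}' is empty")
    mesh = seg.extract_surface(analysed, volume, iso=cfg.threshold)
    centre = fit_sphere_centre(mesh.vertices)

    bead_masks, n_dropped = _artefact_overlap_exclusion(
        parts.beads, parts.rejected, volume.spacing)
    if n_dropped:
        flags.append(f"beads_excluded_artefact_{n_dropped}")
    beads = beads_from_masks(bead_masks, cfg.weight_reference)
    return _ScanFeatures(beads, mesh, centre, n_dropped, tuple(flags))


def _gate_markers(beads: BeadSet, centre: np.ndarray,
                  max_radius: float | None) -> BeadSet:
    if max_radius is None:
        return beads
    dist = np.linalg.norm(beads.centres - centre, axis=1)
    return beads.subset(dist <= max_radius)


def measure_migration(reference: VoxelVolume, target: VoxelVolume,
                      cfg: MeasureConfig) -> MigrationReport:
    """Measure the 6-DoF migration of the analysed implant relative to the
    bone markers between two CT scans.

    Pipeline: segment both scans; extract the analysed implant's surface
    meshes; register target implant onto reference implant (coarse align +
    ICP, or an operator-supplied initial transform); reposition the target
    bead centres with that transform; pair beads by mutual nearest
    neighbour; fit the rigid marker motion in closed form; report its
    inverse (implant relative to markers) decomposed about the configured
    reference point, together with a QC block (condition numbers, ICP
    residual, pair count, stage flags).  Any flagged stage marks the result,
    never silently.
    """
    ref = _extract_features(reference, cfg)
    tgt = _extract_features(target, cfg)
    flags = list(dict.fromkeys(ref.flags + tgt.flags))

    init = cfg.initial_transform
    if init is None:
        init, coarse_flags = coarse_align(tgt.mesh, ref.mesh)
        flags.extend(f for f in coarse_flags
                     if f != "coarse_align_degenerate_axes")
    icp_res = icp(tgt.mesh, ref.mesh, init,
                  tol=cfg.icp_tol, max_iter=cfg.icp_max_iter,
                  sample=cfg.icp_sample, trim=cfg.icp_trim)
    if not icp_res.converged:
        flags.append("icp_not_converged")

    reference_point = (np.asarray(cfg.reference_point, dtype=float)
                       if cfg.reference_point is not None
                       else ref.implant_centre)

    ref_beads = _gate_markers(ref.beads, ref.implant_centre, cfg.marker_max_radius)
    tgt_beads = _gate_markers(
        tgt.beads, invert(icp_res.transform).apply(ref.implant_centre),
        cfg.marker_max_radius)

    pairing = pair_beads(ref_beads, tgt_beads, icp_res.transform,
                         bead_diameter=cfg.bead_diameter)
    flags.extend(pairing.flags)

    cn_ref = condition_number(pairing.reference)
    cn_tgt = condition_number(pairing.target)
    if max(cn_ref, cn_tgt) > 120.0:
        flags.append("condition_number_above_120")

    weights = pairing.reference.grey_masses if cfg.weighted_bead_fit else None
    marker_motion = fit_rigid_paired(pairing.reference.centres,
                                     pairing.target.centres, weights)
    implant_motion = invert(marker_motion)
    result = decompose(implant_motion, reference_point)
    if result.gimbal_lock:
        flags.append("gimbal_lock")

    qc = QCReport(
        condition_number_reference=cn_ref,
        condition_number_target=cn_tgt,
        icp_rms=icp_res.rms_residual,
        icp_converged=icp_res.converged,
        icp_iterations=icp_res.iterations,
        bead_pairs=pairing.n_pairs,
        beads_excluded_reference=ref.n_excluded_beads,
        beads_excluded_target=tgt.n_excluded_beads,
        flags=tuple(flags),
    )
    return MigrationReport(result, implant_motion, qc, pairing)
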