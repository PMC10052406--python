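"""Rigid-body transforms and their 6-degree-of-freedom decomposition.

A migration measurement is ultimately a proper rigid motion (rotation +
translation) of one rigid segment relative to another, expressed in an
anatomical frame: translations along X (proximal-distal), Y (medial-lateral)
and Z (anterior-posterior) in millimetres, and rotations about those axes in
degrees.  All angles in this package use a single fixed convention:
extrinsic X -> Y -> Z Euler angles about right-handed fixed axes, i.e. the
rotation matrix factors as ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``.

Translations are always reported as the displacement of an explicit
``reference_point`` (clinically, the centre of the analysed implant), never
of an implicit origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "MigrationResult",
    "compose",
    "invert",
    "decompose",
    "recompose",
    "random_transform",
]

_ORTHO_TOL = 1e-9
#: |cos(ry)| below this flags gimbal lock in :func:`decompose`.
GIMBAL_COS_THRESHOLD = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation`` in mm space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rot.shape}")
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tr)):
            raise ValueError("non-finite entries in transform")
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > 1e-7:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(rot) - 1.0) > 1e-7:
            raise ValueError("rotation must be proper (det = +1)")
        if err > _ORTHO_TOL:
            # tiny drift from accumulated composition: re-project onto SO(3)
            u, _, vt = np.linalg.svd(rot)
            rot = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, d) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(d, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of mm points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )

    # -- JSON serialisation: 9 row-major rotation entries + 3 translations (mm)
    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation": [float(x) for x in self.translation],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        rot = np.asarray(d["rotation"], dtype=float).reshape(3, 3)
        return cls(rot, np.asarray(d["translation"], dtype=float))

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class MigrationResult:
    """6-DoF decomposition of a rigid motion about ``reference_point``.

    tx, ty, tz -- signed translations (mm) of the reference point along the
    X (proximal-distal), Y (medial-lateral) and Z (anterior-posterior) axes;
    rx, ry, rz -- signed extrinsic X->Y->Z Euler rotations (degrees).
    """

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gimbal_lock: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reference_point",
            np.asarray(self.reference_point, dtype=float).reshape(3),
        )

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    def as_array(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) as a 6-vector (mm, mm, mm, deg, deg, deg)."""
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    def to_dict(self) -> dict:
        return {
            "tx_mm": self.tx, "ty_mm": self.ty, "tz_mm": self.tz,
            "rx_deg": self.rx, "ry_deg": self.ry, "rz_deg": self.rz,
            "reference_point_mm": [float(x) for x in self.reference_point],
            "gimbal_lock": self.gimbal_lock,
        }


AXES = ("tx", "ty", "tz", "rx", "ry", "rz")


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


def invert(t: RigidTransform) -> RigidTransform:
    return RigidTransform(t.rotation.T, -t.rotation.T @ t.translation)


def decompose(t: RigidTransform, reference_point) -> MigrationResult:
    """Split a rigid motion into translations of ``reference_point`` plus
    extrinsic X->Y->Z Euler angles.

    Near gimbal lock (|cos ry| < 1e-6, i.e. ry within ~6e-5 degrees of +-90)
    the rx/rz split is ill-conditioned; the result is returned with
    ``gimbal_lock=True`` rather than failing silently.  The +-2 degree range
    of a migration protocol never approaches this.
    """
    p = np.asarray(reference_point, dtype=float).reshape(3)
    # R = Rz Ry Rx  =>  R[2,0] = -sin(ry)
    cos_ry = float(np.sqrt(max(0.0, 1.0 - t.rotation[2, 0] ** 2)))
    flagged = cos_ry < GIMBAL_COS_THRESHOLD
    rx, ry, rz = Rotation.from_matrix(t.rotation).as_euler("xyz", degrees=True)
    d = t.apply(p) - p
    return MigrationResult(d[0], d[1], d[2], rx, ry, rz,
                           reference_point=p, gimbal_lock=flagged)


def recompose(m: MigrationResult) -> RigidTransform:
    """Inverse of :func:`decompose`: rebuild the rigid motion that moves
    ``m.reference_point`` by (tx, ty, tz) and rotates by (rx, ry, rz)."""
    rot = Rotation.from_euler("xyz", [m.rx, m.ry, m.rz], degrees=True).as_matrix()
    p = m.reference_point
    translation = p + m.translations - rot @ p
    return RigidTransform(rot, translation)


def migration_error(measured: MigrationResult, expected: MigrationResult) -> np.ndarray:
    """Per-axis signed error (measured - expected) as a 6-vector."""
    return measured.as_array() - expected.as_array()


def random_transform(rng: np.random.Generator,
                     max_translation: float = 5.0,
                     max_angle_deg: float = 60.0) -> RigidTransform:
    """Uniform-ish random rigid transform, for tests and oracles."""
    angles = rng.uniform(-max_angle_deg, max_angle_deg, 3)
    rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_translation, max_translation, 3))


def with_reference_point(m: MigrationResult, reference_point) -> MigrationResult:
    """Re-express a migration about a different reference point."""
    return decompose(recompose(m), reference_point)
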