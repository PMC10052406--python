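"""CT volume and surface-mesh IO with consistent world-coordinate metadata.

Volumes are stored as arrays indexed ``values[i, j, k]`` along (x, y, z),
with anisotropic voxel spacing in mm and a world ``origin`` giving the
position of the *centre* of voxel (0, 0, 0).  The world coordinate of index
(i, j, k) is ``origin + (i, j, k) * spacing``.

Supported formats: NIfTI-1 (.nii / .nii.gz) via nibabel, or a raw ``.npy``
array with a JSON sidecar ``{spacing, origin, shape, dtype}``.  Meshes are
STL or PLY via trimesh, vertices in world mm.  Only axis-aligned,
positive-diagonal NIfTI affines are accepted: the method needs consistent
rigid geometry, not full orientation-code support, and silently resampling
an oblique volume would corrupt sub-voxel measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

__all__ = [
    "VoxelVolume",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
]


@dataclass
class VoxelVolume:
    """3D scalar image (HU-like grey values) with spacing and world origin."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel (mm^3)."""
        return float(np.prod(self.spacing))

    def index_to_world(self, ijk) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices (N, 3)."""
        return np.asarray(ijk, dtype=float) * self.spacing + self.origin

    def world_to_index(self, xyz) -> np.ndarray:
        """Fractional voxel indices of world mm points (N, 3)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class SurfaceMesh:
    """Triangulated surface, vertices in world mm, 0-based face indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if n == 0 or len(self.faces) == 0:
            raise ValueError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face index out of range")
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise ValueError(f"{int(degenerate.sum())} degenerate faces")

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def is_watertight(self) -> bool:
        return bool(
            trimesh.Trimesh(self.vertices, self.faces, process=False).is_watertight
        )


_DIAG_TOL = 1e-5


def _check_diagonal_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > _DIAG_TOL * max(1.0, np.abs(np.diag(rot)).max()):
        raise ValueError(
            f"{path}: non-diagonal affine (oblique/rotated volume) not supported; "
            "resample upstream"
        )
    spacing = np.diag(rot).copy()
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine must have positive diagonal, got {spacing}")
    return spacing, affine[:3, 3].copy()


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or raw .npy + JSON-sidecar volume.

    Integer grey values are preserved bit-exactly.
    """
    path = Path(path)
    if path.suffix == ".npy":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        values = np.load(path)
        if values.ndim != 3:
            raise ValueError(f"{path}: volume must be 3D, got {values.ndim}D")
        if "shape" in meta and tuple(meta["shape"]) != values.shape:
            raise ValueError(f"{path}: sidecar shape {meta['shape']} != {values.shape}")
        return VoxelVolume(values, meta["spacing"], meta["origin"])
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        if values.ndim != 3:
            raise ValueError(f"{path}: volume must be 3D, got {values.ndim}D")
        spacing, origin = _check_diagonal_affine(img.affine, path)
        return VoxelVolume(values, spacing, origin)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(volume: VoxelVolume, path) -> None:
    """Write NIfTI or raw .npy + sidecar; round-trips bit-exactly for int16."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, volume.values)
        path.with_suffix(".json").write_text(json.dumps({
            "spacing": [float(x) for x in volume.spacing],
            "origin": [float(x) for x in volume.origin],
            "shape": list(volume.values.shape),
            "dtype": str(volume.values.dtype),
        }))
        return
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(volume.values, volume.affine())
        img.header.set_data_dtype(volume.values.dtype)
        nib.save(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_mesh(path) -> SurfaceMesh:
    """Read an STL or PLY mesh (vertices in mm).

    STL stores unshared triangle soup, so duplicate vertices are merged on
    load; PLY preserves the vertex list exactly.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format: {path}")
    try:
        tm = trimesh.load(str(path), process=(ext == ".stl"))
    except Exception as exc:  # trimesh raises assorted types on corrupt input
        raise ValueError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise ValueError(f"empty or invalid mesh: {path}")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format: {path}")
    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))
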