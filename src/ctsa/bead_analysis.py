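"""Sub-voxel bead localisation and marker-distribution quality.

A 1 mm bead spans only a few anisotropic voxels, so its mask is never
spherical; the bead centre is instead the centre of mass of the
above-reference grey values in the masked cluster, which recovers the
centre to a small fraction of a voxel thanks to partial-volume weighting.

The condition number of a bead set -- the ratio of largest to smallest
singular value of the mean-centred coordinate matrix -- measures how
well-distributed the markers are for rigid-body fitting; near-coplanar or
collinear sets blow it up.  Values above 120 are conventionally flagged as
unreliable marker distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .kinematics import RigidTransform
from .segmentation import VoxelMask

__all__ = [
    "BeadSet",
    "BeadPairing",
    "CONDITION_NUMBER_LIMIT",
    "bead_centre",
    "beads_from_masks",
    "condition_number",
    "singular_values",
    "pair_beads",
]

CONDITION_NUMBER_LIMIT = 120.0


@dataclass
class BeadSet:
    """Ordered sub-voxel bead centres (mm, world frame) with their
    above-reference grey-mass weights."""

    centres: np.ndarray
    grey_masses: np.ndarray
    labels: np.ndarray | None = None
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 3)
        self.grey_masses = np.asarray(self.grey_masses, dtype=float).reshape(-1)
        if len(self.centres) != len(self.grey_masses):
            raise ValueError("centres and grey_masses length mismatch")
        if not np.all(np.isfinite(self.centres)):
            raise ValueError("non-finite bead centre")
        if self.labels is None:
            self.labels = np.arange(len(self.centres))
        else:
            self.labels = np.asarray(self.labels)

    def __len__(self) -> int:
        return len(self.centres)

    def subset(self, sel) -> "BeadSet":
        return BeadSet(self.centres[sel], self.grey_masses[sel],
                       self.labels[sel], self.flags)

    def transformed(self, t: RigidTransform) -> "BeadSet":
        return BeadSet(t.apply(self.centres), self.grey_masses.copy(),
                       self.labels.copy(), self.flags)


def bead_centre(mask: VoxelMask, background_reference: float = 0.0) -> np.ndarray:
    """Grey-value-weighted centroid (mm) of a bead mask.

    Weights are grey value minus ``background_reference`` (the configured
    bone/background level, so the noise floor does not bias the centroid),
    floored at zero.
    """
    w = np.clip(mask.grey_values - background_reference, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all bead weights are zero at the given reference level")
    return (w[:, None] * mask.world_coordinates).sum(axis=0) / total


def grey_mass(mask: VoxelMask, background_reference: float = 0.0) -> float:
    """Total above-reference grey mass (HU x voxel) of a mask."""
    return float(np.clip(mask.grey_values - background_reference, 0.0, None).sum())


def beads_from_masks(masks, background_reference: float = 0.0) -> BeadSet:
    centres = [bead_centre(m, background_reference) for m in masks]
    masses = [grey_mass(m, background_reference) for m in masks]
    return BeadSet(np.asarray(centres).reshape(-1, 3), masses)


def singular_values(beads: BeadSet) -> np.ndarray:
    """Singular values of the mean-centred N x 3 coordinate matrix (logged
    alongside the condition number so alternative scalings can be derived)."""
    centred = beads.centres - beads.centres.mean(axis=0)
    return np.linalg.svd(centred, compute_uv=False)


def condition_number(beads: BeadSet) -> float:
    """sigma_1 / sigma_3 of the centred coordinate matrix; infinite for
    coplanar or collinear sets.  Values above 120 indicate a marker
    distribution too degenerate for reliable rigid-body fitting."""
    if len(beads) < 3:
        raise ValueError("condition number needs at least 3 beads")
    sv = singular_values(beads)
    if sv[2] <= 1e-12 * sv[0]:
        return float("inf")
    return float(sv[0] / sv[2])


@dataclass
class BeadPairing:
    """Mutual-nearest-neighbour bead correspondence between two scans.

    ``target`` centres are expressed in the reference frame (the implant
    pre-alignment has been applied); pairing is a bijection on the retained
    subset and unmatched beads are dropped symmetrically.
    """

    reference: BeadSet
    target: BeadSet
    flags: tuple = ()
    dropped_reference: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    dropped_target: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_pairs(self) -> int:
        return len(self.reference)


def pair_beads(ref: BeadSet, tgt: BeadSet, prealign: RigidTransform,
               bead_diameter: float = 1.0,
               max_distance: float | None = None) -> BeadPairing:
    """Pair beads between scans by mutual nearest neighbour after applying
    the implant-matching ``prealign`` (target frame -> reference frame).

    Bead spacing (several mm) vastly exceeds protocol displacements
    (<= 2 mm / 2 degrees), so mutual NN is exact in practice; a target bead
    contested by two reference beads at comparable distance (within one
    bead diameter) is flagged as ambiguous, never guessed.  Fewer than
    three pairs is an error.
    """
    if len(ref) == 0 or len(tgt) == 0:
        raise ValueError("empty bead set")
    aligned = prealign.apply(tgt.centres)
    tree_t = cKDTree(aligned)
    tree_r = cKDTree(ref.centres)
    d_rt, nn_rt = tree_t.query(ref.centres)
    _, nn_tr = tree_r.query(aligned)

    flags: list[str] = []
    # ambiguity: two reference beads contesting one target at similar range
    by_target: dict[int, list[int]] = {}
    for i, j in enumerate(nn_rt):
        by_target.setdefault(int(j), []).append(i)
    for j, claimants in by_target.items():
        if len(claimants) > 1:
            dists = sorted(d_rt[i] for i in claimants)
            if dists[1] - dists[0] < bead_diameter:
                flags.append(f"ambiguous_pairing_target_{j}")

    ref_idx = [i for i, j in enumerate(nn_rt)
               if nn_tr[j] == i
               and (max_distance is None or d_rt[i] <= max_distance)]
    tgt_idx = [int(nn_rt[i]) for i in ref_idx]
    if len(ref_idx) < 3:
        raise ValueError(f"only {len(ref_idx)} bead pairs (need >= 3)")

    ref_paired = ref.subset(np.asarray(ref_idx))
    tgt_paired = BeadSet(aligned[tgt_idx], tgt.grey_masses[tgt_idx],
                         tgt.labels[tgt_idx], tgt.flags)
    return BeadPairing(
        ref_paired, tgt_paired, tuple(flags),
        dropped_reference=np.setdiff1d(np.arange(len(ref)), ref_idx),
        dropped_target=np.setdiff1d(np.arange(len(tgt)), tgt_idx),
    )


def beadset_to_csv(beads: BeadSet, path) -> None:
    """Write (label, x, y, z, grey_mass) rows."""
    import pandas as pd

    pd.DataFrame({
        "label": beads.labels,
        "x_mm": beads.centres[:, 0],
        "y_mm": beads.centres[:, 1],
        "z_mm": beads.centres[:, 2],
        "grey_mass": beads.grey_masses,
    }).to_csv(path, index=False)
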