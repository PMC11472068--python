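"""Rigid-body mathematics: least-squares superposition, RMSD, distance matrices.

All coordinates are in Angstroms, stored as float64 ``(n, 3)`` arrays.
Rotations are proper (determinant +1); reflections are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["RigidTransform", "kabsch", "rmsd", "pairwise_distance_matrix"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation: ``x -> R @ x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` point array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def kabsch(reference: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of *mobile* onto *reference*.

    Returns the transform minimizing the RMSD of the transformed mobile
    points against the reference, and that minimum RMSD.  The reflection
    branch of the SVD solution is excluded by sign-correcting the smallest
    singular value, so the rotation determinant is always +1.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    if ref.shape != mob.shape:
        raise ValueError(f"point counts differ: {ref.shape[0]} vs {mob.shape[0]}")
    if ref.shape[0] == 0:
        raise ValueError("cannot superimpose empty point sets")

    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    H = (mob - mob_c).T @ (ref - ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    transform = RigidTransform(R, t)
    return transform, rmsd(ref, transform.apply(mob))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired point sets; no fitting."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("paired point sets must have equal size")
    if a.shape[0] == 0:
        raise ValueError("rmsd of empty point sets is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix, entry (i, j) = |a_i - b_j|."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("distance matrix of empty point set")
    return cdist(a, b)
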