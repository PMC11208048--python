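"""Rigid-body geometry primitives shared across the package.

Superpositions are least-squares (Kabsch) fits returning proper rotations;
dihedrals follow the IUPAC sign convention with angles in (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation applied first)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Both arrays are (n, 3) with matched rows, n >= 3 for a well-defined
    rotation (n >= 1 is accepted; degenerate cases fall back to the
    SVD solution, which is still a proper rotation).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"matched (n, 3) coordinate sets required, got {mobile.shape} vs {target.shape}"
        )
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return RigidTransform(rot, mu_t - rot @ mu_m)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between matched coordinate sets (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"matched coordinate sets required, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty selection")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Kabsch fit plus the post-fit RMSD over the fitted selection."""
    tf = kabsch(mobile, target)
    return tf, rmsd(tf.apply(mobile), target)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (radians) defined by four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    return float(np.arctan2(y, x))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)
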