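"""Low-level rigid-body geometry: Kabsch superposition, batched RMSD, dihedrals.

These primitives are shared by the alphabet (fragment clustering) and the
refinement stage (hit superposition).  The public home of ``kabsch_superpose``
is :mod:`safold.refine`, which re-exports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "kabsch_superpose", "pairwise_rmsd", "dihedral"]

# Singular-value gap below which the point cloud is treated as rank-deficient
# (collinear / planar-degenerate); the fit is still returned but flagged.
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t``.

    ``degenerate`` is set when the input points were rank-deficient
    (e.g. collinear), in which case the rotation is one of a continuum of
    optimal solutions.
    """

    rotation: np.ndarray
    translation: np.ndarray
    degenerate: bool = field(default=False, compare=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``P`` onto ``Q`` (Kabsch algorithm).

    Returns the proper rigid transform minimising ``sum ||R P_i + t - Q_i||^2``
    and the RMSD of the residuals.  Reflections are corrected by flipping the
    sign of the smallest singular vector when ``det < 0``.

    Parameters
    ----------
    P, Q : (n, 3) arrays, n >= 3
        Paired coordinates in Angstrom.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to superpose, got {n}")

    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    P0 = P - cP
    Q0 = Q - cQ

    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    degenerate = bool(S[1] < _DEGENERATE_TOL * max(S[0], 1.0)) or bool(
        S[2] < _DEGENERATE_TOL * max(S[0], 1.0)
    )

    t = cQ - R @ cP
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return RigidTransform(rotation=R, translation=t, degenerate=degenerate), rmsd


def pairwise_rmsd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Superposition RMSD between every row-pair of two fragment stacks.

    ``A`` is ``(na, m, 3)``, ``B`` is ``(nb, m, 3)``; returns ``(na, nb)``.
    Uses the singular-value identity: after centering,
    ``m * msd = ||A||^2 + ||B||^2 - 2 * (s1 + s2 +/- s3)`` with the sign of
    ``s3`` flipped when the optimal rotation would be a reflection.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m = A.shape[1]
    A0 = A - A.mean(axis=1, keepdims=True)
    B0 = B - B.mean(axis=1, keepdims=True)
    na, nb = A0.shape[0], B0.shape[0]
    # cross-covariance for every pair: (na, nb, 3, 3)
    H = np.einsum("aki,bkj->abij", A0, B0)
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    s3 = np.where(det < 0.0, -S[..., 2], S[..., 2])
    normA = (A0**2).sum(axis=(1, 2))[:, None]
    normB = (B0**2).sum(axis=(1, 2))[None, :]
    msd = (normA + normB - 2.0 * (S[..., 0] + S[..., 1] + s3)) / m
    return np.sqrt(np.maximum(msd, 0.0))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (radians, IUPAC sign convention) of four points."""
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return float(np.arctan2(y, x))
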