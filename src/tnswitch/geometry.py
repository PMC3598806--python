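"""Exact geometric primitives shared by every trajectory metric.

Distances, least-squares rigid superposition (Kabsch), dihedral angles in
the IUPAC sign convention, and Rodrigues axis rotations.  Angles are in
degrees at every API boundary; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "distance",
    "kabsch_superpose",
    "dihedral",
    "rotate_about_axis",
]


class DegenerateGeometryError(ValueError):
    """Raised when the input point configuration makes an operation undefined."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> R @ x + t.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1;
    ``translation`` is in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be a proper rotation (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (N, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def distance(p, q) -> float:
    """Euclidean distance between two 3-vectors, in Angstrom."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("distance requires finite coordinates")
    return float(np.linalg.norm(p - q))


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimising the (optionally weighted)
    RMSD, and that minimal RMSD.  Reflections are excluded by the usual
    determinant sign correction, so a mirror-image point set keeps a
    strictly positive residual.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a rank-deficient (collinear/coincident)
        configuration, where the optimal rotation is not unique.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ P
    ct = w @ Q
    P0 = P - cm
    Q0 = Q - ct
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # Rank < 2 means all points (after centering) lie on a line or a point:
    # the in-plane rotation about that line is unconstrained.
    if np.sum(S > 1e-10 * max(S[0], 1e-300)) < 2:
        raise DegenerateGeometryError(
            "degenerate (collinear or coincident) point configuration"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    transform = RigidTransform(R, t)
    resid = transform.apply(P) - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", resid, resid))))
    return transform, rmsd


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: with b1 = p2-p1, b2 = p3-p2, b3 = p4-p3,
    n1 = b1 x b2, n2 = b2 x b3, the angle is
    atan2((n1 x n2) . b2_hat, n1 . n2).  Invariant under rigid motion.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise DegenerateGeometryError("dihedral undefined: central bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError(
            "dihedral undefined: three consecutive points are collinear"
        )
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    x = np.dot(n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def rotate_about_axis(points, axis_point, axis_dir, angle_deg: float) -> np.ndarray:
    """Rotate points by ``angle_deg`` about the axis through ``axis_point``
    along ``axis_dir`` (Rodrigues formula).  Distances to the axis are
    preserved to machine precision."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(axis_point, dtype=float)
    k = np.asarray(axis_dir, dtype=float)
    nk = np.linalg.norm(k)
    if nk < 1e-12:
        raise ValueError("rotation axis direction must be nonzero")
    k = k / nk
    theta = np.radians(angle_deg)
    v = p - a
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rotated = (
        v * cos_t
        + np.cross(np.broadcast_to(k, v.shape), v) * sin_t
        + np.outer(v @ k, k) * (1.0 - cos_t)
    )
    out = rotated + a
    if np.asarray(points).ndim == 1:
        return out[0]
    return out
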