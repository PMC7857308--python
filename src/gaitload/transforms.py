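"""Landmark-driven spatial transforms used for bone-geometry personalization.

Template bone surfaces are carried onto subject-specific geometry by a
composite map: a least-squares affine registration, a tri-harmonic radial
basis function (RBF) interpolation that matches paired anatomical landmarks
exactly, and a reverse rigid-body step that re-expresses the morphed
geometry in the source (template) segment frame.  The same composite is
applied to muscle attachment sites so that personalized models inherit
subject-specific lines of action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq, solve, svd


class DegenerateGeometryError(ValueError):
    """Raised when a landmark configuration cannot support the requested fit."""


def _as_points(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {p.shape}")
    return p


@dataclass
class AffineTransform:
    """y = A @ x + t with a general (not necessarily orthogonal) linear part."""

    A: np.ndarray
    t: np.ndarray

    def apply(self, points) -> np.ndarray:
        return _as_points(points) @ self.A.T + self.t

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class RigidTransform:
    """y = R @ x + t with R a proper rotation (det +1)."""

    R: np.ndarray
    t: np.ndarray
    reflection_corrected: bool = False

    def apply(self, points) -> np.ndarray:
        return _as_points(points) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def triharmonic(r: np.ndarray) -> np.ndarray:
    """Tri-harmonic kernel phi(r) = r^3 (the 3-D biharmonic spline of order 2)."""
    return r ** 3


@dataclass
class RBFTransform:
    """Polynomial-augmented RBF interpolant mapping R^3 -> R^3.

    The map is y(x) = sum_i w_i phi(|x - c_i|) + B @ [1, x]; the first-order
    polynomial term absorbs any exact affine component, so for targets that
    are an affine image of the sources the RBF weights vanish identically.
    Interpolation is exact at the control points (no smoothing).
    """

    centers: np.ndarray          # (n, 3)
    weights: np.ndarray          # (n, 3)
    poly: np.ndarray             # (4, 3): rows = [const; x; y; z] coefficients
    kernel: str = "triharmonic"

    def apply(self, points) -> np.ndarray:
        p = _as_points(points)
        r = np.linalg.norm(p[:, None, :] - self.centers[None, :, :], axis=2)
        phi = triharmonic(r)
        poly = np.hstack([np.ones((len(p), 1)), p]) @ self.poly
        return phi @ self.weights + poly

    @property
    def affine_part(self) -> AffineTransform:
        return AffineTransform(self.poly[1:].T.copy(), self.poly[0].copy())


@dataclass
class CompositeTransform:
    """Ordered composition; ``apply`` runs the stages left to right."""

    stages: list = field(default_factory=list)

    def apply(self, points) -> np.ndarray:
        p = _as_points(points)
        for stage in self.stages:
            p = stage.apply(p)
        return p


def fit_affine(source_landmarks, target_landmarks) -> AffineTransform:
    """Least-squares affine registration of paired landmarks.

    Minimizes sum ||A s_i + t - g_i||^2.  Requires at least four
    non-coplanar correspondences; a coplanar source set leaves the linear
    part underdetermined and is rejected rather than silently regularized.
    """
    src = _as_points(source_landmarks)
    tgt = _as_points(target_landmarks)
    if src.shape != tgt.shape:
        raise ValueError("source and target landmark sets differ in shape")
    if len(src) < 4:
        raise DegenerateGeometryError("affine fit needs >= 4 correspondences")
    X = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(X, tol=1e-9 * max(1.0, np.abs(X).max())) < 4:
        raise DegenerateGeometryError(
            "source landmarks are coplanar/degenerate; affine fit is rank-deficient"
        )
    coef, *_ = lstsq(X, tgt)
    return AffineTransform(A=coef[:3].T.copy(), t=coef[3].copy())


def fit_rbf(source_landmarks, target_landmarks, kernel: str = "triharmonic") -> RBFTransform:
    """Exact tri-harmonic RBF interpolation of paired landmarks.

    Solves the standard augmented system
        [K  P] [W]   [G]
        [P' 0] [B] = [0]
    with K_ij = phi(|s_i - s_j|) and P = [1 | s].  The orthogonality side
    conditions P' W = 0 make the interpolant exactly reproduce affine target
    fields through the polynomial block alone.
    """
    if kernel != "triharmonic":
        raise ValueError(f"unsupported kernel {kernel!r}")
    src = _as_points(source_landmarks)
    tgt = _as_points(target_landmarks)
    if src.shape != tgt.shape:
        raise ValueError("source and target landmark sets differ in shape")
    n = len(src)
    if n < 4:
        raise DegenerateGeometryError("RBF fit needs >= 4 correspondences")
    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    if np.any(d[~np.eye(n, dtype=bool)] < 1e-12):
        raise DegenerateGeometryError("duplicated source landmarks")
    K = triharmonic(d)
    P = np.hstack([np.ones((n, 1)), src])
    M = np.zeros((n + 4, n + 4))
    M[:n, :n] = K
    M[:n, n:] = P
    M[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError mostly
        raise DegenerateGeometryError(f"singular RBF system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateGeometryError("singular RBF system (collinear landmarks?)")
    residual = np.abs(K @ sol[:n] + P @ sol[n:] - tgt).max()
    scale = max(np.linalg.norm(tgt.max(0) - tgt.min(0)), 1.0)
    if residual > 1e-6 * scale:
        raise DegenerateGeometryError(
            f"RBF interpolation residual {residual:.3g} exceeds tolerance; "
            "landmark configuration is numerically degenerate"
        )
    return RBFTransform(centers=src.copy(), weights=sol[:n], poly=sol[n:], kernel=kernel)


def reverse_rigid(morphed_landmarks, source_landmarks) -> RigidTransform:
    """Least-squares rigid alignment of morphed geometry back onto the source.

    Classic SVD Procrustes solution constrained to a proper rotation; if the
    unconstrained optimum is a reflection the smallest singular direction is
    flipped and the transform is flagged ``reflection_corrected``.
    """
    src = _as_points(morphed_landmarks)
    tgt = _as_points(source_landmarks)
    if src.shape != tgt.shape:
        raise ValueError("landmark sets differ in shape")
    if len(src) < 3:
        raise DegenerateGeometryError("rigid fit needs >= 3 correspondences")
    src_c = src - src.mean(0)
    tgt_c = tgt - tgt.mean(0)
    if np.linalg.matrix_rank(src_c, tol=1e-10 * max(1.0, np.abs(src_c).max())) < 2:
        raise DegenerateGeometryError("collinear landmarks; rotation is underdetermined")
    U, _, Vt = svd(tgt_c.T @ src_c)
    flipped = False
    D = np.eye(3)
    if np.linalg.det(U @ Vt) < 0:
        D[2, 2] = -1.0
        flipped = True
    R = U @ D @ Vt
    t = tgt.mean(0) - R @ src.mean(0)
    return RigidTransform(R=R, t=t, reflection_corrected=flipped)
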