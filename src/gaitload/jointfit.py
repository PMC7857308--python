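"""Analytical joint-axis and joint-center estimation from bone surface points.

Personalized joint parameters come from least-squares primitive fits to
selected regions of subject bone geometry: a sphere to the femoral head
(hip center) and cylinders to the femoral condyles and talar trochlea
(knee and ankle hinge axes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lstsq
from scipy.optimize import least_squares

from .transforms import DegenerateGeometryError, _as_points


@dataclass
class JointFit:
    kind: str                      # "sphere" | "cylinder"
    center: np.ndarray             # sphere center, or a point on the cylinder axis (m)
    radius: float                  # m
    rms_residual: float            # m
    axis_direction: np.ndarray | None = None   # unit vector, cylinder only

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


def fit_sphere(points) -> JointFit:
    """Least-squares sphere through >= 4 non-coplanar points.

    Uses the algebraic linearization |p|^2 = 2 c.p + (r^2 - |c|^2), which is
    exact for noiseless samples, followed by a geometric Gauss-Newton refine
    of sum (|p - c| - r)^2.
    """
    p = _as_points(points)
    if len(p) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    X = np.hstack([2 * p, np.ones((len(p), 1))])
    scale = max(1.0, np.abs(p).max())
    if np.linalg.matrix_rank(X - X.mean(0), tol=1e-9 * scale) < 3:
        raise DegenerateGeometryError("points are coplanar/collinear; sphere fit degenerate")
    b = (p ** 2).sum(1)
    coef, *_ = lstsq(X, b)
    c0 = coef[:3]
    r0 = float(np.sqrt(max(coef[3] + c0 @ c0, 1e-16)))

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    sol = least_squares(resid, np.r_[c0, r0], method="lm", xtol=1e-14, ftol=1e-14)
    c, r = sol.x[:3], float(sol.x[3])
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return JointFit(kind="sphere", center=c, radius=abs(r), rms_residual=rms)


def _cylinder_residual(x, p):
    # x = [cx, cy (point on axis, in axis-orthogonal plane coords), theta, phi, r]
    theta, phi = x[2], x[3]
    a = np.array([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])
    # basis orthogonal to a
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    c = x[0] * e1 + x[1] * e2
    d = p - c
    radial = d - (d @ a)[:, None] * a[None, :]
    return np.linalg.norm(radial, axis=1) - x[4]


def fit_cylinder(points) -> JointFit:
    """Least-squares circular cylinder through >= 6 points.

    Initialization: the axis starts from the principal component of the
    point cloud (surface samples of a joint cylinder are elongated along its
    axis), the radius from the mean radial distance; a Levenberg-Marquardt
    refinement then minimizes the geometric radial residual.
    """
    p = _as_points(points)
    if len(p) < 6:
        raise DegenerateGeometryError("cylinder fit needs >= 6 points")
    centered = p - p.mean(0)
    scale = max(1.0, np.abs(p).max())
    if np.linalg.matrix_rank(centered, tol=1e-9 * scale) < 2:
        raise DegenerateGeometryError("collinear points; cylinder fit degenerate")
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    a0 = Vt[0]
    theta0 = float(np.arccos(np.clip(a0[2], -1, 1)))
    phi0 = float(np.arctan2(a0[1], a0[0]))
    ref = np.array([1.0, 0.0, 0.0]) if abs(a0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a0, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a0, e1)
    m = p.mean(0)
    d = centered - (centered @ a0)[:, None] * a0[None, :]
    r0 = float(np.linalg.norm(d, axis=1).mean())
    x0 = np.array([m @ e1, m @ e2, theta0, phi0, max(r0, 1e-6)])
    sol = least_squares(_cylinder_residual, x0, args=(p,), method="lm",
                        xtol=1e-14, ftol=1e-14, max_nfev=2000)
    theta, phi = sol.x[2], sol.x[3]
    a = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    c = sol.x[0] * e1 + sol.x[1] * e2
    # place the axis point at the centroid's axial station for reportability
    c = c + ((p.mean(0) - c) @ a) * a
    rms = float(np.sqrt(np.mean(_cylinder_residual(sol.x, p) ** 2)))
    return JointFit(kind="cylinder", center=c, radius=abs(float(sol.x[4])),
                    rms_residual=rms, axis_direction=a)
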