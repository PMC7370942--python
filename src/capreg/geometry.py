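"""Rigid/similarity/anisotropic-scale transforms and small geometric solvers.

Coordinate convention shared by every module: right-handed, millimetres,
origin at the head centre, +x to the subject's right (left–right axis),
+y anterior (anterior–posterior axis), +z superior (vertical).  This is the
same axis ordering as MNI/RAS, so MNI tables drop in without permutation.
"""

from __future__ import annotations

import dataclasses
import random

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError

__all__ = [
    "CapTransform",
    "euler_rotation",
    "umeyama",
    "umeyama_batch",
    "min_enclosing_circle",
]


@dataclasses.dataclass(frozen=True)
class CapTransform:
    """A cap-on-head (or head-to-MNI) transform: rotation, per-axis scale,
    translation.

    Applied as ``p' = S @ R @ p + t`` with ``S = diag(scale_lr, scale_ap,
    scale_vert)`` — the axes the cap can physically scale along are
    left–right (x) and anterior–posterior (y); the vertical scale is 1
    unless explicitly freed.
    """

    rotation: np.ndarray
    scale_ap: float = 1.0
    scale_lr: float = 1.0
    scale_vert: float = 1.0
    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3))
    residual_mm: float | None = None

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidParameterError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"rotation determinant must be +1, got {np.linalg.det(R)}")
        if not (np.allclose(R @ R.T, np.eye(3), atol=1e-8)):
            raise InvalidParameterError("rotation must be orthonormal")
        for name in ("scale_ap", "scale_lr", "scale_vert"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def scale_matrix(self) -> np.ndarray:
        return np.diag([self.scale_lr, self.scale_ap, self.scale_vert])

    @property
    def linear(self) -> np.ndarray:
        """The 3x3 linear part ``S @ R``."""
        return self.scale_matrix @ self.rotation

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = pts.reshape(-1, 3) @ self.linear.T + self.translation
        return out[0] if single else out

    @classmethod
    def identity(cls) -> "CapTransform":
        return cls(rotation=np.eye(3))


def euler_rotation(angles_deg) -> np.ndarray:
    """Rotation matrix from extrinsic x-y-z Euler angles in degrees."""
    return Rotation.from_euler("xyz", np.asarray(angles_deg, float),
                               degrees=True).as_matrix()


def umeyama(src: np.ndarray, dst: np.ndarray):
    """Closed-form similarity fit (rotation, uniform scale, translation)
    minimising ``sum ||s R src + t - dst||^2``.

    Returns ``(R, s, t)``. Proper rotation enforced (det +1).
    """
    R, s, t = umeyama_batch(src[None], dst[None])
    return R[0], float(s[0]), t[0]


def umeyama_batch(src: np.ndarray, dst: np.ndarray):
    """Vectorised similarity fits over a stack of correspondences.

    src, dst: (m, k, 3) stacks of k matched points.
    Returns R (m, 3, 3), s (m,), t (m, 3) such that dst ≈ s R src + t.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    k = src.shape[1]
    mu_s = src.mean(axis=1, keepdims=True)
    mu_d = dst.mean(axis=1, keepdims=True)
    sc = src - mu_s
    dc = dst - mu_d
    # cross-covariance: (1/k) sum dc_i sc_i^T  -> (m, 3, 3)
    cov = np.einsum("mki,mkj->mij", dc, sc) / k
    U, D, Vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("mij,mjk->mik", U, Vt))
    fix = np.ones((src.shape[0], 3))
    fix[:, 2] = np.sign(det)
    fix[det == 0, 2] = 1.0
    R = np.einsum("mij,mj,mjk->mik", U, fix, Vt)
    var_s = (sc ** 2).sum(axis=(1, 2)) / k
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (D * fix).sum(axis=1) / var_s
    s = np.where(np.isfinite(s) & (s > 0), s, 1.0)
    t = mu_d[:, 0, :] - s[:, None] * np.einsum("mij,mj->mi", R, mu_s[:, 0, :])
    return R, s, t


# ---------------------------------------------------------------------------
# Exact minimum enclosing circle (Welzl, move-to-front, expected O(n)).


def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(a, b, c):
    """Circumscribed circle of three points; None if collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    centre = np.array([ux, uy])
    return centre, float(np.linalg.norm(a - centre))


def _in_circle(circle, p, eps=1e-9):
    c, r = circle
    return np.linalg.norm(p - c) <= r + eps


def min_enclosing_circle(points: np.ndarray, seed: int = 0):
    """Exact smallest enclosing circle of 2-D points.

    Returns ``(center, radius)``. Deterministic: the internal shuffle uses
    the given seed.
    """
    pts = [np.asarray(p, float) for p in np.atleast_2d(points)]
    if not pts:
        raise InvalidParameterError("need at least one point")
    rng = random.Random(seed)
    rng.shuffle(pts)

    circle = (pts[0].copy(), 0.0)
    for i, p in enumerate(pts[1:], start=1):
        if _in_circle(circle, p):
            continue
        # p on boundary
        circle = (p.copy(), 0.0)
        for j in range(i):
            q = pts[j]
            if _in_circle(circle, q):
                continue
            # p, q on boundary
            circle = _circle_two(p, q)
            for k in range(j):
                r = pts[k]
                if _in_circle(circle, r):
                    continue
                c3 = _circle_three(p, q, r)
                if c3 is not None:
                    circle = c3
                else:
                    # collinear triple: fall back to widest pair
                    best = circle
                    for a, b in ((p, q), (p, r), (q, r)):
                        cand = _circle_two(a, b)
                        if cand[1] > best[1]:
                            best = cand
                    circle = best
    return circle
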