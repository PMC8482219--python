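"""Epipolar diagnostics between the eye plane and the viewed plane.

Treating the eye-feature plane and the screen as a two-view system, the
fundamental matrix maps an eye feature to an epipolar line on the screen;
the common intersection of those lines — the epipole — localizes the
(possibly virtual) eye-camera relative to the screen.  After camera-location
compensation the epipole should sit near the screen center, which is the
paper-trail diagnostic this module provides.

Because calibration grids are close to homographic (nearly coplanar
correspondences), the estimate can be poorly constrained; a degeneracy ratio
built from the design-matrix singular values is reported so the caller knows
when the epipole is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import Correspondences

__all__ = [
    "FundamentalMatrix",
    "estimate_fundamental",
    "epipole_of",
    "epipolar_line",
]


@dataclass(frozen=True)
class FundamentalMatrix:
    """Rank-2, unit-norm fundamental matrix with convention
    ``dst_h^T F src_h = 0`` (src = eye plane, dst = viewed plane).

    ``degeneracy_ratio`` is the ratio of the two smallest design-matrix
    singular values (s9/s8): values near 1 flag a near-homographic point
    configuration whose epipole is unreliable.
    """

    F: np.ndarray
    residual: float = 0.0
    degeneracy_ratio: float = 0.0

    def __post_init__(self):
        F = np.asarray(self.F, float)
        if F.shape != (3, 3):
            raise ValueError("fundamental matrix must be 3x3")
        u, s, vt = np.linalg.svd(F)
        s = s.copy()
        s[2] = 0.0  # enforce rank 2
        F = u @ np.diag(s) @ vt
        F = F / np.linalg.norm(F)
        object.__setattr__(self, "F", F)

    @property
    def unreliable(self) -> bool:
        return self.degeneracy_ratio > 0.5


def estimate_fundamental(c: Correspondences) -> FundamentalMatrix:
    """Hartley-normalized 8-point estimate of F from (eye, screen) pairs.

    Correspondences that are exactly homographic leave F under-determined;
    the fit is then still returned but flagged via ``degeneracy_ratio``
    rather than raised, since real calibration grids are only approximately
    homographic.
    """
    if len(c) < 8:
        raise ValueError("estimate_fundamental needs at least 8 correspondences")

    def norm_transform(p):
        centroid = p.mean(axis=0)
        d = np.linalg.norm(p - centroid, axis=1).mean()
        s = np.sqrt(2.0) / d
        return np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]])

    Ts, Td = norm_transform(c.src), norm_transform(c.dst)
    src = np.column_stack([c.src, np.ones(len(c))]) @ Ts.T
    dst = np.column_stack([c.dst, np.ones(len(c))]) @ Td.T
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    A = np.column_stack(
        [u * x, u * y, u, v * x, v * y, v, x, y, np.ones_like(x)]
    )
    _, s, vt = np.linalg.svd(A)
    ratio = float(s[-1] / s[-2]) if s[-2] > 0 else 1.0
    Fn = vt[-1].reshape(3, 3)
    F = Td.T @ Fn @ Ts
    fm = FundamentalMatrix(F, degeneracy_ratio=ratio)
    # report mean symmetric epipolar distance of the input pairs
    lines = epipolar_line(fm, c.src)
    d = np.abs(np.sum(lines[:, :2] * c.dst, axis=1) + lines[:, 2])
    return FundamentalMatrix(fm.F, residual=float(d.mean()), degeneracy_ratio=ratio)


def epipole_of(F: FundamentalMatrix, plane: str = "dst") -> tuple[np.ndarray, bool]:
    """Epipole of the viewed plane (``plane='dst'``, default) or the eye
    plane (``'src'``), dehomogenized.

    Returns ``(point, at_infinity)``; for an at-infinity epipole the point is
    the direction vector instead of a Euclidean position.
    """
    M = F.F.T if plane == "dst" else F.F
    _, _, vt = np.linalg.svd(M)
    e = vt[-1]
    w = e[2]
    if abs(w) < 1e-9 * np.linalg.norm(e[:2]):
        d = e[:2] / np.linalg.norm(e[:2])
        return d, True
    return e[:2] / w, False


def epipolar_line(F: FundamentalMatrix, p: np.ndarray) -> np.ndarray:
    """Epipolar line(s) ``(a, b, c)`` on the viewed plane for eye-plane
    point(s) ``p``, normalized so a² + b² = 1."""
    p = np.asarray(p, float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    lines = np.column_stack([pts, np.ones(len(pts))]) @ F.F.T
    n = np.linalg.norm(lines[:, :2], axis=1, keepdims=True)
    lines = lines / n
    return lines[0] if single else lines
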