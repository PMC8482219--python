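"""Interpolation-based gaze mappings.

Two classic 2-D→2-D calibration transforms used throughout remote eye
tracking:

* the second-order polynomial
  ``x' = a0 x² + a1 y² + a2 xy + a3 x + a4 y + a5`` (and likewise ``y'``
  with coefficients ``b``), fitted per axis by linear least squares, and
* the planar homography, fitted by the Hartley-normalized direct linear
  transform (DLT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Poly2Map",
    "HomographyMap",
    "Correspondences",
    "SingularFitError",
    "fit_poly2",
    "apply_poly2",
    "fit_homography",
    "apply_homography",
]


class SingularFitError(np.linalg.LinAlgError):
    """The calibration geometry is degenerate (rank-deficient design)."""


@dataclass(frozen=True)
class Correspondences:
    """Paired 2-D points (src_i ↔ dst_i)."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "src", np.atleast_2d(np.asarray(self.src, float)))
        object.__setattr__(self, "dst", np.atleast_2d(np.asarray(self.dst, float)))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src and dst must both be (n, 2)")
        uniq = np.unique(self.src, axis=0)
        if len(uniq) != len(self.src):
            raise ValueError("duplicate src points")

    def __len__(self) -> int:
        return len(self.src)


def _design_matrix(p: np.ndarray) -> np.ndarray:
    x, y = p[:, 0], p[:, 1]
    return np.column_stack([x * x, y * y, x * y, x, y, np.ones_like(x)])


@dataclass(frozen=True)
class Poly2Map:
    """Second-order polynomial map with per-axis coefficients a0..a5, b0..b5
    ordered as (x², y², xy, x, y, 1)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, float))
        object.__setattr__(self, "b", np.asarray(self.b, float))
        if self.a.shape != (6,) or self.b.shape != (6,):
            raise ValueError("coefficient vectors must have length 6")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("coefficients must be finite")

    @classmethod
    def identity(cls) -> "Poly2Map":
        return cls(np.array([0, 0, 0, 1, 0, 0.0]), np.array([0, 0, 0, 0, 1, 0.0]))

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return apply_poly2(self, p)

    def to_json(self) -> str:
        names_a = [f"a{i}" for i in range(6)]
        names_b = [f"b{i}" for i in range(6)]
        return json.dumps(
            {"type": "poly2",
             **dict(zip(names_a, self.a.tolist())),
             **dict(zip(names_b, self.b.tolist()))},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Poly2Map":
        d = json.loads(text)
        return cls(np.array([d[f"a{i}"] for i in range(6)]),
                   np.array([d[f"b{i}"] for i in range(6)]))


def fit_poly2(c: Correspondences) -> Poly2Map:
    """Least-squares fit of the second-order polynomial (QR-based lstsq).

    Requires at least 6 correspondences of full design rank; with exactly 6
    nondegenerate points the fit interpolates.
    """
    if len(c) < 6:
        raise ValueError("fit_poly2 needs at least 6 correspondences")
    A = _design_matrix(c.src)
    if np.linalg.matrix_rank(A) < 6:
        raise SingularFitError("degenerate calibration grid for poly2 fit")
    coef, *_ = np.linalg.lstsq(A, c.dst, rcond=None)
    return Poly2Map(coef[:, 0], coef[:, 1])


def apply_poly2(m: Poly2Map, p: np.ndarray) -> np.ndarray:
    """Evaluate the polynomial map at one point or an (n, 2) array."""
    p = np.asarray(p, float)
    single = p.ndim == 1
    A = _design_matrix(np.atleast_2d(p))
    out = np.column_stack([A @ m.a, A @ m.b])
    return out[0] if single else out


@dataclass(frozen=True)
class HomographyMap:
    """Planar homography, stored with unit Frobenius norm (sign fixed so the
    bottom-right entry is non-negative)."""

    H: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.H, float)
        if H.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(H)) < 1e-15 * np.linalg.norm(H) ** 3:
            raise SingularFitError("homography matrix is singular")
        H = H / np.linalg.norm(H)
        if H[2, 2] < 0:
            H = -H
        object.__setattr__(self, "H", H)

    @classmethod
    def identity(cls) -> "HomographyMap":
        return cls(np.eye(3))

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return apply_homography(self, p)

    @property
    def normalized(self) -> np.ndarray:
        """Display form with bottom-right entry 1 (when nonzero)."""
        h22 = self.H[2, 2]
        return self.H / h22 if abs(h22) > 1e-12 else self.H

    def to_json(self) -> str:
        return json.dumps({"type": "homography", "H": self.H.tolist()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HomographyMap":
        return cls(np.array(json.loads(text)["H"]))


def _hartley_normalization(p: np.ndarray) -> np.ndarray:
    """Similarity transform taking points to zero centroid and mean distance
    sqrt(2) (isotropic pre-normalization)."""
    centroid = p.mean(axis=0)
    d = np.linalg.norm(p - centroid, axis=1).mean()
    if d < 1e-12:
        raise SingularFitError("coincident points")
    s = np.sqrt(2.0) / d
    return np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )


def fit_homography(c: Correspondences) -> HomographyMap:
    """Hartley-normalized DLT homography estimate (algebraic least squares)."""
    if len(c) < 4:
        raise ValueError("fit_homography needs at least 4 correspondences")
    Ts = _hartley_normalization(c.src)
    Td = _hartley_normalization(c.dst)
    src = np.column_stack([c.src, np.ones(len(c))]) @ Ts.T
    dst = np.column_stack([c.dst, np.ones(len(c))]) @ Td.T
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    zero = np.zeros_like(x)
    one = np.ones_like(x)
    rows_u = np.column_stack([x, y, one, zero, zero, zero, -u * x, -u * y, -u])
    rows_v = np.column_stack([zero, zero, zero, x, y, one, -v * x, -v * y, -v])
    A = np.vstack([rows_u, rows_v])
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-10 * s[0]:
        raise SingularFitError("degenerate correspondences for homography")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return HomographyMap(H)


def apply_homography(m: HomographyMap, p: np.ndarray) -> np.ndarray:
    """Apply the homography with perspective division; raises on points
    mapped to infinity (w = 0)."""
    p = np.asarray(p, float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ m.H.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12 * np.linalg.norm(m.H)):
        raise ValueError("point maps to infinity (w = 0)")
    out = hom[:, :2] / w[:, None]
    return out[0] if single else out
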