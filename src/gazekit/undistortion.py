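"""Eye-feature distribution undistortion.

After eye-camera location compensation, the normalized pupil-center
distribution still bends like the image of a grid through a distorting lens
(typically barrel-shaped), because the pupil center does not stay on a plane
while the eyeball rotates.  This module models that residual error with the
standard calibrated-camera distortion model — rational radial (k1..k6),
tangential (p1, p2) and thin-prism (s1..s4) terms — and fits the
coefficients from the nine calibration correspondences by damped nonlinear
least squares.

With r² = xn² + yn²:

    rho   = (1 + k1 r² + k2 r⁴ + k3 r⁶) / (1 + k4 r² + k5 r⁴ + k6 r⁶)
    tau_x = 2 p1 xn yn + p2 (r² + 2 xn²)
    tau_y = p1 (r² + 2 yn²) + 2 p2 xn yn
    phi_x = s1 r² + s2 r⁴
    phi_y = s3 r² + s4 r⁴

and the corrected feature is ``pn* = pn · rho + tau + phi`` componentwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DistortionModel",
    "DEFAULT_FREE_COEFFICIENTS",
    "apply_distortion_model",
    "fit_distortion",
]

COEFFICIENT_NAMES = (
    "k1", "k2", "k3", "k4", "k5", "k6", "p1", "p2", "s1", "s2", "s3", "s4",
)

# 8 free parameters against the 18 equations of a 3x3 calibration grid; the
# rational radial tail k3..k6 is not identifiable from 9 points and stays 0
# unless explicitly unlocked.
DEFAULT_FREE_COEFFICIENTS = ("k1", "k2", "p1", "p2", "s1", "s2", "s3", "s4")


@dataclass(frozen=True)
class DistortionModel:
    """Radial + tangential + prism distortion coefficients.

    The all-zero model is the exact identity correction.
    """

    k: np.ndarray = field(default_factory=lambda: np.zeros(6))
    p: np.ndarray = field(default_factory=lambda: np.zeros(2))
    s: np.ndarray = field(default_factory=lambda: np.zeros(4))
    residual: float = 0.0
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, float))
        object.__setattr__(self, "p", np.asarray(self.p, float))
        object.__setattr__(self, "s", np.asarray(self.s, float))
        if self.k.shape != (6,) or self.p.shape != (2,) or self.s.shape != (4,):
            raise ValueError("expected 6 radial, 2 tangential, 4 prism coefficients")
        for arr in (self.k, self.p, self.s):
            if not np.isfinite(arr).all():
                raise ValueError("coefficients must be finite")

    @property
    def coefficients(self) -> dict[str, float]:
        vals = np.concatenate([self.k, self.p, self.s])
        return dict(zip(COEFFICIENT_NAMES, vals.tolist()))

    def __call__(self, p_n: np.ndarray) -> np.ndarray:
        return apply_distortion_model(p_n, self)

    def to_json(self) -> str:
        return json.dumps({"type": "distortion", **self.coefficients}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DistortionModel":
        d = json.loads(text)
        return cls.from_coefficients({n: d.get(n, 0.0) for n in COEFFICIENT_NAMES})

    @classmethod
    def from_coefficients(cls, coeffs: dict[str, float]) -> "DistortionModel":
        vals = np.array([coeffs.get(n, 0.0) for n in COEFFICIENT_NAMES])
        return cls(k=vals[:6], p=vals[6:8], s=vals[8:12])


def apply_distortion_model(p_n: np.ndarray, m: DistortionModel) -> np.ndarray:
    """Apply the correction ``pn* = pn · rho + tau + phi`` to one point or an
    (n, 2) array of normalized features."""
    p_n = np.asarray(p_n, float)
    single = p_n.ndim == 1
    pts = np.atleast_2d(p_n)
    x, y = pts[:, 0], pts[:, 1]
    r2 = x * x + y * y
    r4 = r2 * r2
    r6 = r4 * r2
    k1, k2, k3, k4, k5, k6 = m.k
    p1, p2 = m.p
    s1, s2, s3, s4 = m.s
    denom = 1.0 + k4 * r2 + k5 * r4 + k6 * r6
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("rational radial denominator vanishes")
    rho = (1.0 + k1 * r2 + k2 * r4 + k3 * r6) / denom
    tau_x = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    tau_y = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    phi_x = s1 * r2 + s2 * r4
    phi_y = s3 * r2 + s4 * r4
    out = np.column_stack([x * rho + tau_x + phi_x, y * rho + tau_y + phi_y])
    return out[0] if single else out


def fit_distortion(
    normalized: np.ndarray,
    ideal: np.ndarray,
    free: tuple[str, ...] = DEFAULT_FREE_COEFFICIENTS,
    max_iter: int = 500,
) -> DistortionModel:
    """Fit distortion coefficients mapping observed normalized features onto
    the ideal calibration grid.

    Minimizes ``sum_i || correct(p_n_i) - g_i ||²`` over the selected free
    coefficients with Levenberg–Marquardt (zero initialization,
    deterministic).  A non-converged fit is returned flagged rather than
    raised.
    """
    normalized = np.atleast_2d(np.asarray(normalized, float))
    ideal = np.atleast_2d(np.asarray(ideal, float))
    if normalized.shape != ideal.shape:
        raise ValueError("normalized and ideal grids must pair up")
    if 2 * len(normalized) < len(free):
        raise ValueError("not enough correspondences for the free coefficient set")
    unknown = set(free) - set(COEFFICIENT_NAMES)
    if unknown:
        raise ValueError(f"unknown coefficients: {sorted(unknown)}")

    idx = [COEFFICIENT_NAMES.index(n) for n in free]

    def unpack(theta: np.ndarray) -> DistortionModel:
        vals = np.zeros(12)
        vals[idx] = theta
        return DistortionModel(k=vals[:6], p=vals[6:8], s=vals[8:12])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (apply_distortion_model(normalized, unpack(theta)) - ideal).ravel()

    res = least_squares(
        residuals,
        np.zeros(len(free)),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
        max_nfev=max_iter * (len(free) + 1),
    )
    model = unpack(res.x)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    converged = bool(res.status > 0)
    return DistortionModel(
        k=model.k, p=model.p, s=model.s, residual=rms, converged=converged
    )
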