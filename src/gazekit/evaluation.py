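"""Gaze-error computation and accuracy statistics.

Errors are reported as visual angles: an on-screen offset ``d`` (mm or px ×
pixel pitch) at viewing distance ``D`` subtends ``atan(d / D)``.  The
headline statistic is the *high-accuracy probability*: a Gaussian is fitted
to the signed per-axis gaze-error sample and its probability mass inside the
band (−0.5°, +0.5°) is reported — the probability that a single gaze
estimate is high-accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ErrorSet",
    "GaussianAccuracy",
    "DEFAULT_BAND",
    "pixels_to_degrees",
    "offset_to_degrees",
    "gaze_errors",
    "fit_gaussian",
    "high_accuracy_probability",
    "kde_representative",
    "filter_outliers",
]

DEFAULT_BAND = (-0.5, 0.5)


def pixels_to_degrees(offset_px, pixel_size_mm: float, distance_mm: float):
    """Visual angle (degrees) of an on-screen offset given in pixels,
    via the right-angled triangle at the stated viewing distance."""
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    return np.degrees(np.arctan(np.asarray(offset_px, float) * pixel_size_mm / distance_mm))


def offset_to_degrees(offset_mm, distance_mm: float):
    """Visual angle (degrees) of an on-screen offset given in millimetres."""
    return pixels_to_degrees(offset_mm, 1.0, distance_mm)


@dataclass
class ErrorSet:
    """Per-target signed gaze errors with their angular conversions."""

    ex_deg: np.ndarray
    ey_deg: np.ndarray
    magnitude_deg: np.ndarray
    ex_raw: np.ndarray
    ey_raw: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.magnitude_deg)

    @property
    def mean_deg(self) -> float:
        return float(np.mean(self.magnitude_deg))


def gaze_errors(
    estimates: np.ndarray,
    targets: np.ndarray,
    distance_mm: float,
    pixel_size_mm: float = 1.0,
    meta: dict | None = None,
) -> ErrorSet:
    """Signed per-axis and Euclidean gaze errors, raw and in degrees.

    ``estimates`` and ``targets`` are paired (n, 2) arrays in the same screen
    unit; ``pixel_size_mm`` converts that unit to mm (1.0 when already mm).
    """
    estimates = np.atleast_2d(np.asarray(estimates, float))
    targets = np.atleast_2d(np.asarray(targets, float))
    if estimates.shape != targets.shape:
        raise ValueError("estimates and targets must pair up")
    diff = estimates - targets
    mag = np.linalg.norm(diff, axis=1)
    return ErrorSet(
        ex_deg=pixels_to_degrees(diff[:, 0], pixel_size_mm, distance_mm),
        ey_deg=pixels_to_degrees(diff[:, 1], pixel_size_mm, distance_mm),
        magnitude_deg=pixels_to_degrees(mag, pixel_size_mm, distance_mm),
        ex_raw=diff[:, 0],
        ey_raw=diff[:, 1],
        meta=meta or {},
    )


@dataclass(frozen=True)
class GaussianAccuracy:
    """Gaussian fit of a signed gaze-error sample plus the probability mass
    inside the high-accuracy band."""

    mu: float
    sigma: float
    band: tuple[float, float] = DEFAULT_BAND
    n: int = 0

    @property
    def p_high(self) -> float:
        return high_accuracy_probability(self)


def fit_gaussian(errors: np.ndarray, band: tuple[float, float] = DEFAULT_BAND) -> GaussianAccuracy:
    """Maximum-likelihood Gaussian fit (sample mean, population standard
    deviation) of a 1-D signed error sample."""
    errors = np.asarray(errors, float).ravel()
    if len(errors) < 1:
        raise ValueError("need at least one observation")
    mu = float(np.mean(errors))
    sigma = float(np.std(errors))
    return GaussianAccuracy(mu=mu, sigma=sigma, band=band, n=len(errors))


def fit_gaussian_mixture(
    errors: np.ndarray, band=DEFAULT_BAND, max_iter: int = 200, tol: float = 1e-10
):
    """Two-component 1-D Gaussian mixture (EM, deterministic quantile
    initialization) for visibly multi-peaked error distributions.

    Returns a list of (weight, GaussianAccuracy), heaviest component first.
    Only meant for explicit use when a single Gaussian clearly misfits.
    """
    x = np.asarray(errors, float).ravel()
    if len(x) < 4:
        raise ValueError("mixture fit needs at least 4 observations")
    mu = np.quantile(x, [0.25, 0.75])
    sigma = np.full(2, max(np.std(x), 1e-12))
    w = np.array([0.5, 0.5])
    ll_prev = -np.inf
    for _ in range(max_iter):
        resp = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sigma[None, :])
        total = resp.sum(axis=1, keepdims=True)
        total[total == 0] = 1e-300
        ll = float(np.sum(np.log(total)))
        resp = resp / total
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, 1e-24))
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    order = np.argsort(-w)
    return [
        (float(w[i]), GaussianAccuracy(float(mu[i]), float(sigma[i]), band, len(x)))
        for i in order
    ]


def high_accuracy_probability(g: GaussianAccuracy) -> float:
    """Gaussian probability mass inside the band, Φ((hi−μ)/σ) − Φ((lo−μ)/σ).

    A zero-variance sample is a point mass: probability 1 if μ is inside the
    band, else 0.
    """
    lo, hi = g.band
    if g.sigma < 0:
        raise ValueError("sigma must be non-negative")
    if g.sigma == 0:
        return float(lo <= g.mu <= hi)
    return float(stats.norm.cdf(hi, g.mu, g.sigma) - stats.norm.cdf(lo, g.mu, g.sigma))


def kde_representative(sample: np.ndarray, bandwidth: str | float = "silverman") -> np.ndarray:
    """Most representative 2-D point of a fixation sample: the observed
    point with the highest Gaussian kernel density estimate.

    This is the 150-to-1 reduction applied per viewed target: the mode of the
    sample cloud is robust to stray samples (blinks, glint dropouts) that
    would bias the mean.
    """
    sample = np.atleast_2d(np.asarray(sample, float))
    if len(sample) < 5:
        raise ValueError("KDE reduction needs at least 5 samples")
    if np.allclose(sample, sample[0]):
        return sample[0].copy()
    try:
        kde = stats.gaussian_kde(sample.T, bw_method=bandwidth)
        dens = kde(sample.T)
    except np.linalg.LinAlgError:
        # Degenerate (collinear) cloud: fall back to 1-D density along the
        # principal axis.
        centered = sample - sample.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        kde = stats.gaussian_kde(proj, bw_method=bandwidth)
        dens = kde(proj)
    return sample[int(np.argmax(dens))].copy()


def filter_outliers(
    trials: list[ErrorSet],
    max_mean_offset_deg: float = 5.0,
    sigma_factor: float = 3.0,
):
    """Two-stage outlier filter used before the accuracy analysis.

    Stage 1 drops whole trials whose mean gaze offset exceeds
    ``max_mean_offset_deg``; stage 2 drops individual estimations further
    than ``sigma_factor`` standard deviations from the pooled mean (the
    99.7th percentile rule at the default 3σ).  Returns the filtered trials
    (each with a boolean keep-mask applied) and a report dict.
    """
    stage1 = []
    dropped_trials = 0
    for t in trials:
        if t.mean_deg > max_mean_offset_deg:
            dropped_trials += 1
        else:
            stage1.append(t)
    pooled = np.concatenate([t.magnitude_deg for t in stage1]) if stage1 else np.array([])
    removed_samples = 0
    filtered = []
    if len(pooled):
        mean, std = pooled.mean(), pooled.std()
        for t in trials:
            if t.mean_deg > max_mean_offset_deg:
                continue
            keep = np.abs(t.magnitude_deg - mean) <= sigma_factor * std if std > 0 else np.ones(len(t), bool)
            removed_samples += int((~keep).sum())
            filtered.append(
                ErrorSet(
                    ex_deg=t.ex_deg[keep],
                    ey_deg=t.ey_deg[keep],
                    magnitude_deg=t.magnitude_deg[keep],
                    ex_raw=t.ex_raw[keep],
                    ey_raw=t.ey_raw[keep],
                    meta=dict(t.meta),
                )
            )
    report = {
        "trials_in": len(trials),
        "trials_removed": dropped_trials,
        "samples_removed": removed_samples,
        "samples_out": int(sum(len(t) for t in filtered)),
    }
    if not filtered or report["samples_out"] == 0:
        import warnings

        warnings.warn("outlier filtering removed all data", stacklevel=2)
    return filtered, report
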