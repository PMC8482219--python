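"""End-to-end gaze-estimation pipelines and the camera-sweep evaluation.

Six pipelines are evaluated, mirroring the simulated/user studies:

======  ===========================================================
name    stages
======  ===========================================================
Hes     homography: eye features → screen
Hes+    compensation (Πe→Πn polynomial), homography Πn → screen
Hes*    compensation, undistortion, homography → screen
Pes     second-order polynomial: eye features → screen
Pes+    compensation, polynomial Πn → screen
Pes*    compensation, undistortion, polynomial → screen
======  ===========================================================

Every pipeline is calibrated on the 3×3 calibration subset only and then
applied to the full target grid.  The sweep evaluator repeats this per
camera position, accumulating per-position mean angular errors and the
pooled sufficient statistics for the Gaussian high-accuracy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compensation import (
    METHODS,
    NormalizationMap,
    fit_normalization,
    ideal_normalized_grid,
    normalize_features,
)
from .evaluation import (
    DEFAULT_BAND,
    GaussianAccuracy,
    fit_gaussian,
    high_accuracy_probability,
    offset_to_degrees,
)
from .mapping import Correspondences, fit_homography, fit_poly2
from .simulator import FeatureSet, Scene, batch_observe, calibration_indices, grid_targets
from .undistortion import DistortionModel, apply_distortion_model, fit_distortion

__all__ = [
    "GazeMapper",
    "calibrate",
    "SweepEvaluation",
    "evaluate_sweep",
    "analyze_session",
    "infer_calibration_indices",
    "METHODS",
]


@dataclass(frozen=True)
class GazeMapper:
    """A calibrated gaze-estimation pipeline; ``predict`` maps raw eye
    features to screen coordinates."""

    method: str
    final_map: object
    normalization: NormalizationMap | None = None
    distortion: DistortionModel | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        p = np.asarray(features, float)
        if self.normalization is not None:
            p = self.normalization(p)
        if self.distortion is not None:
            p = apply_distortion_model(p, self.distortion)
        return self.final_map(p)


def _validate_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def calibrate(
    method: str,
    features: FeatureSet,
    calib_indices: np.ndarray,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> GazeMapper:
    """Calibrate one of the six pipelines on the calibration subset of a
    feature set."""
    _validate_method(method)
    calib_indices = np.asarray(calib_indices, int)
    feats = features.features[calib_indices]
    targets = features.targets[calib_indices]

    nmap = None
    dist = None
    p = feats
    if method.endswith("+") or method.endswith("*"):
        nmap = fit_normalization(features, calib_indices, x_range, y_range)
        p = nmap(p)
        if method.endswith("*"):
            dist = fit_distortion(p, nmap.calib_grid_n)
            p = apply_distortion_model(p, dist)
    corr = Correspondences(p, targets)
    final = fit_homography(corr) if method.startswith("H") else fit_poly2(corr)
    return GazeMapper(method=method, final_map=final, normalization=nmap, distortion=dist)


def _estimate_all(
    features: np.ndarray,
    targets: np.ndarray,
    calib_idx: np.ndarray,
    methods: tuple[str, ...],
    grid_n: np.ndarray,
) -> dict[str, np.ndarray]:
    """Calibrate every requested pipeline on one session (raw arrays) and
    return its screen estimates for all targets.  Intermediate fits shared
    between pipelines are computed once."""
    calib_feats = features[calib_idx]
    calib_targets = targets[calib_idx]
    out: dict[str, np.ndarray] = {}

    needs_norm = any(m.endswith(("+", "*")) for m in methods)
    norm_all = norm_calib = None
    if needs_norm:
        poly_n = fit_poly2(Correspondences(calib_feats, grid_n))
        norm_all = poly_n(features)
        norm_calib = norm_all[calib_idx]

    undist_all = undist_calib = None
    if any(m.endswith("*") for m in methods):
        dist = fit_distortion(norm_calib, grid_n)
        undist_all = apply_distortion_model(norm_all, dist)
        undist_calib = undist_all[calib_idx]

    for m in methods:
        if m.endswith("*"):
            src_all, src_calib = undist_all, undist_calib
        elif m.endswith("+"):
            src_all, src_calib = norm_all, norm_calib
        else:
            src_all, src_calib = features, calib_feats
        corr = Correspondences(src_calib, calib_targets)
        fitted = fit_homography(corr) if m.startswith("H") else fit_poly2(corr)
        out[m] = fitted(src_all)
    return out


@dataclass
class _Pooled:
    """Running sufficient statistics of a signed error component."""

    n: int = 0
    s1: float = 0.0
    s2: float = 0.0

    def add(self, values: np.ndarray) -> None:
        self.n += values.size
        self.s1 += float(values.sum())
        self.s2 += float(np.square(values).sum())

    def gaussian(self, band=DEFAULT_BAND) -> GaussianAccuracy:
        mu = self.s1 / self.n
        var = max(self.s2 / self.n - mu * mu, 0.0)
        return GaussianAccuracy(mu=mu, sigma=float(np.sqrt(var)), band=band, n=self.n)


@dataclass
class SweepEvaluation:
    """Results of evaluating pipelines over a camera-position sweep."""

    positions: np.ndarray
    methods: tuple[str, ...]
    per_position_mean: dict[str, np.ndarray]  # mean angular error (deg)
    pooled: dict[str, dict[str, _Pooled]]     # method → axis → stats
    band: tuple[float, float] = DEFAULT_BAND
    errors: dict[str, dict[str, np.ndarray]] | None = None  # raw, if kept
    meta: dict = field(default_factory=dict)

    def gaussian(self, method: str, axis: str) -> GaussianAccuracy:
        """Gaussian fit of the pooled signed errors of one axis (x, y, z)."""
        return self.pooled[method][axis].gaussian(self.band)

    def band_probability(self, method: str, axis: str) -> float:
        return high_accuracy_probability(self.gaussian(method, axis))

    def gaussian_band_table(self) -> pd.DataFrame:
        """Per-method Gaussian band probabilities per axis plus their
        average (the layout of the study's accuracy table)."""
        rows = {}
        for m in self.methods:
            px = self.band_probability(m, "x")
            py = self.band_probability(m, "y")
            pz = self.band_probability(m, "z")
            rows[m] = {
                "Gaze_X": px,
                "Gaze_Y": py,
                "Gaze_Z": pz,
                "Average": (px + py + pz) / 3.0,
            }
        return pd.DataFrame(rows).T

    def summary(self) -> pd.DataFrame:
        """Per-method grand mean / min / max of the per-position means."""
        rows = {}
        for m in self.methods:
            pm = self.per_position_mean[m]
            rows[m] = {
                "grand_mean_deg": pm.mean(),
                "min_deg": pm.min(),
                "max_deg": pm.max(),
                "std_deg": pm.std(ddof=1) if len(pm) > 1 else 0.0,
            }
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-position mean errors."""
        recs = []
        for m in self.methods:
            for pos, err in zip(self.positions, self.per_position_mean[m]):
                recs.append(
                    {"method": m, "cam_x": pos[0], "cam_y": pos[1],
                     "cam_z": pos[2], "mean_error_deg": err}
                )
        return pd.DataFrame(recs)


def evaluate_sweep(
    scene: Scene,
    camera_positions: np.ndarray,
    targets: np.ndarray | tuple[int, int] = (21, 21),
    calib_idx: np.ndarray | None = None,
    methods: tuple[str, ...] = METHODS,
    band: tuple[float, float] = DEFAULT_BAND,
    refraction: bool = True,
    keep_errors: bool = False,
    chunk: int = 32,
) -> SweepEvaluation:
    """Run the full simulation + calibration + estimation + error analysis
    over a set of camera positions.

    For every position the eye/target protocol is identical: the eye fixates
    each target, the camera observes the (refracted) pupil center, each
    requested pipeline is calibrated on the 3×3 subset and applied to all
    targets.  Angular errors use the eye-to-screen viewing distance.
    """
    for m in methods:
        _validate_method(m)
    if isinstance(targets, tuple):
        shape = targets
        targets = grid_targets(scene.screen, *shape)
        if calib_idx is None:
            calib_idx = calibration_indices(*shape)
    if calib_idx is None:
        raise ValueError("explicit targets need explicit calibration indices")
    calib_idx = np.asarray(calib_idx, int)
    camera_positions = np.atleast_2d(np.asarray(camera_positions, float))
    distance = float(scene.eye.eyeball_center[2])  # eye → screen plane
    grid_n = ideal_normalized_grid(
        targets[calib_idx], scene.screen.x_range, scene.screen.y_range
    )

    m_pos = len(camera_positions)
    per_pos = {m: np.empty(m_pos) for m in methods}
    pooled = {m: {ax: _Pooled() for ax in "xyz"} for m in methods}
    raw = {m: {ax: [] for ax in "xyz"} for m in methods} if keep_errors else None

    for start in range(0, m_pos, chunk):
        cams = camera_positions[start : start + chunk]
        feats = batch_observe(scene, cams, targets, refraction=refraction, chunk=chunk)
        for j in range(len(cams)):
            estimates = _estimate_all(feats[j], targets, calib_idx, methods, grid_n)
            for m, est in estimates.items():
                # embed both points in the screen plane so the signed error
                # is a full 3-vector (its z-component measures any
                # off-plane residual, zero for planar estimates)
                diff = est - targets
                diff3 = np.column_stack([diff, np.zeros(len(diff))])
                err_deg = offset_to_degrees(diff3, distance)
                mag_deg = offset_to_degrees(np.linalg.norm(diff, axis=1), distance)
                per_pos[m][start + j] = mag_deg.mean()
                for k, ax in enumerate("xyz"):
                    pooled[m][ax].add(err_deg[:, k])
                    if keep_errors:
                        raw[m][ax].append(err_deg[:, k])

    if keep_errors:
        raw = {m: {ax: np.concatenate(v) for ax, v in d.items()} for m, d in raw.items()}
    return SweepEvaluation(
        positions=camera_positions,
        methods=tuple(methods),
        per_position_mean=per_pos,
        pooled=pooled,
        band=band,
        errors=raw,
        meta={
            "scene": scene.to_dict(),
            "n_targets": len(targets),
            "calibration_indices": calib_idx.tolist(),
            "viewing_distance_mm": distance,
            "refraction": refraction,
        },
    )


def infer_calibration_indices(targets: np.ndarray) -> np.ndarray:
    """Indices of the records closest to a 3×3 grid spanning the target
    bounding box (8 boundary targets + center), for sessions whose grid
    layout is not known a priori."""
    targets = np.atleast_2d(np.asarray(targets, float))
    xs = [targets[:, 0].min(), targets[:, 0].mean(), targets[:, 0].max()]
    ys = [targets[:, 1].min(), targets[:, 1].mean(), targets[:, 1].max()]
    idx = []
    for y in ys:
        for x in xs:
            d = np.linalg.norm(targets - np.array([x, y]), axis=1)
            idx.append(int(np.argmin(d)))
    if len(set(idx)) < 9:
        raise ValueError("could not locate 9 distinct calibration targets")
    return np.array(idx)


def analyze_session(
    features: FeatureSet,
    methods: tuple[str, ...] = METHODS,
    distance_mm: float = 450.0,
    pixel_size_mm: float = 0.27675,
    band: tuple[float, float] = DEFAULT_BAND,
    samples_per_target: int | None = None,
    use_glints: bool | None = None,
    calib_idx: np.ndarray | None = None,
    max_mean_offset_deg: float = 5.0,
):
    """Evaluate the six pipelines on one recorded (or fixture) session.

    Mirrors the user-study analysis: frames are grouped per target, the quad
    glints (when present) normalize each pupil center, KDE reduces the
    per-target sample cloud to its most representative point, the pipelines
    are calibrated on the 3×3 subset, and signed errors feed the Gaussian
    high-accuracy analysis.  Returns a report dict (per-method mean absolute
    errors, Gaussian band table, outlier counts).
    """
    from .compensation import glint_normalize_set
    from .evaluation import ErrorSet, filter_outliers, gaze_errors, kde_representative

    if use_glints is None:
        use_glints = features.glints is not None and np.isfinite(features.glints).any()
    working = glint_normalize_set(features) if use_glints else features

    # group frames by identical target coordinates, preserving first-seen order
    targets, inverse = np.unique(working.targets, axis=0, return_inverse=True)
    order = np.argsort([np.flatnonzero(inverse == g)[0] for g in range(len(targets))])
    reduced_feats = np.empty((len(targets), 2))
    reduced_targets = np.empty((len(targets), 2))
    for slot, g in enumerate(order):
        sel = (inverse == g) & working.valid
        if not np.any(sel):
            raise ValueError("a target has no valid frames after glint normalization")
        cloud = working.features[sel]
        reduced_feats[slot] = (
            kde_representative(cloud) if len(cloud) >= 5 else cloud.mean(axis=0)
        )
        reduced_targets[slot] = targets[g]
    reduced = FeatureSet(reduced_targets, reduced_feats, meta=dict(features.meta))

    if calib_idx is None:
        calib_idx = infer_calibration_indices(reduced.targets)

    report = {
        "n_frames": int(len(features)),
        "n_targets": int(len(reduced)),
        "glint_normalized": bool(use_glints),
        "band_deg": list(band),
        "methods": {},
        "gaussian_band": {},
    }
    for m in methods:
        mapper = calibrate(m, reduced, calib_idx)
        est = mapper.predict(reduced.features)
        err = gaze_errors(est, reduced.targets, distance_mm, pixel_size_mm,
                          meta={"method": m})
        kept, filt = filter_outliers([err], max_mean_offset_deg=max_mean_offset_deg)
        pooled_x = np.concatenate([e.ex_deg for e in kept]) if kept else np.array([])
        pooled_y = np.concatenate([e.ey_deg for e in kept]) if kept else np.array([])
        entry = {
            "mean_abs_error_deg": float(err.mean_deg),
            "outlier_filter": filt,
        }
        if len(pooled_x):
            gx, gy = fit_gaussian(pooled_x, band), fit_gaussian(pooled_y, band)
            report["gaussian_band"][m] = {
                "Gaze_X": high_accuracy_probability(gx),
                "Gaze_Y": high_accuracy_probability(gy),
                "Average": 0.5 * (high_accuracy_probability(gx) + high_accuracy_probability(gy)),
            }
            entry["gaussian"] = {
                "mu_x": gx.mu, "sigma_x": gx.sigma,
                "mu_y": gy.mu, "sigma_y": gy.sigma,
            }
        report["methods"][m] = entry
    return report
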