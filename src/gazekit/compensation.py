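"""Eye-camera location compensation.

The eye-camera's pose skews the raw pupil-center distribution on the image
plane.  Fitting the second-order polynomial from the calibration eye
features onto an ideal grid in the normalized plane Πn = [−1, +1]² acts like
virtually re-mounting the camera on the eye's optical axis: the normalized
distribution becomes camera-independent (up to the residual barrel-shaped
curvature that the undistortion stage removes).

For real recordings, the quad-glint normalization maps the pupil center
through the homography sending the four corneal reflections to a fixed unit
square, removing head-translation effects before the polynomial stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import (
    Correspondences,
    HomographyMap,
    Poly2Map,
    apply_homography,
    apply_poly2,
    fit_homography,
    fit_poly2,
)
from .simulator import FeatureSet

__all__ = [
    "NormalizationMap",
    "ideal_normalized_grid",
    "fit_normalization",
    "normalize_features",
    "glint_normalize",
    "METHODS",
]

#: The six evaluated pipelines: homography / polynomial, each traditional
#: (Hes, Pes), with camera-location compensation (+), and with compensation
#: plus undistortion (*).
METHODS = ("Hes", "Hes+", "Hes*", "Pes", "Pes+", "Pes*")


def ideal_normalized_grid(
    targets: np.ndarray,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> np.ndarray:
    """Linearly rescale screen-space calibration targets into [−1, +1]² so
    the screen corners land on the normalized-square corners."""
    targets = np.atleast_2d(np.asarray(targets, float))
    out = np.empty_like(targets)
    out[:, 0] = 2.0 * (targets[:, 0] - x_range[0]) / (x_range[1] - x_range[0]) - 1.0
    out[:, 1] = 2.0 * (targets[:, 1] - y_range[0]) / (y_range[1] - y_range[0]) - 1.0
    return out


@dataclass(frozen=True)
class NormalizationMap:
    """The fitted Πe → Πn polynomial together with the ideal grid its
    calibration targets map to."""

    poly: Poly2Map
    calib_grid_n: np.ndarray

    def __post_init__(self):
        grid = np.atleast_2d(np.asarray(self.calib_grid_n, float))
        if np.any(np.abs(grid) > 1.0 + 1e-9):
            raise ValueError("ideal normalized grid must lie within [-1, 1]^2")
        object.__setattr__(self, "calib_grid_n", grid)

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return apply_poly2(self.poly, features)


def _screen_ranges(features: FeatureSet):
    scene = features.meta.get("scene")
    if scene is not None:
        scr = scene["screen"]
        return tuple(scr["x_range"]), tuple(scr["y_range"])
    t = features.targets
    return (t[:, 0].min(), t[:, 0].max()), (t[:, 1].min(), t[:, 1].max())


def fit_normalization(
    features: FeatureSet,
    calib_indices: np.ndarray,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> NormalizationMap:
    """Fit the compensation polynomial on the calibration subset.

    The same records used for gaze-mapping calibration serve here: their eye
    features are regressed onto the ideal normalized grid obtained by
    rescaling the calibration targets from the screen range to [−1, +1]².
    """
    calib_indices = np.asarray(calib_indices, int)
    if len(calib_indices) < 9:
        raise ValueError("normalization requires at least 9 calibration records")
    if x_range is None or y_range is None:
        xr, yr = _screen_ranges(features)
        x_range = x_range or xr
        y_range = y_range or yr
    calib_targets = features.targets[calib_indices]
    calib_feats = features.features[calib_indices]
    grid_n = ideal_normalized_grid(calib_targets, x_range, y_range)
    poly = fit_poly2(Correspondences(calib_feats, grid_n))
    return NormalizationMap(poly=poly, calib_grid_n=grid_n)


def normalize_features(nmap: NormalizationMap, features: FeatureSet) -> FeatureSet:
    """Map every eye feature into Πn; targets pass through unchanged."""
    out = features.with_features(apply_poly2(nmap.poly, features.features))
    out.meta["space"] = "normalized"
    return out


_UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def glint_normalize(pupil: np.ndarray, glints: np.ndarray) -> np.ndarray:
    """Quad-glint normalization: map the pupil center through the homography
    sending the four (enumerated, corner-ordered) glints to the unit square
    [0, 1]².  Exactly invariant to projective transforms applied jointly to
    pupil and glints.
    """
    glints = np.asarray(glints, float)
    if glints.shape != (4, 2):
        raise ValueError("expected exactly 4 glints")
    if not np.isfinite(glints).all():
        raise ValueError("missing glint coordinates")
    H = fit_homography(Correspondences(glints, _UNIT_SQUARE))
    return apply_homography(H, np.asarray(pupil, float))


def glint_normalize_set(features: FeatureSet) -> FeatureSet:
    """Apply quad-glint normalization record-wise; records with missing or
    degenerate glints are flagged invalid."""
    if features.glints is None:
        raise ValueError("feature set carries no glints")
    out = np.full_like(features.features, np.nan)
    valid = features.valid.copy()
    for i in range(len(features)):
        if not valid[i] or not np.isfinite(features.glints[i]).all():
            valid[i] = False
            continue
        try:
            out[i] = glint_normalize(features.features[i], features.glints[i])
        except (ValueError, np.linalg.LinAlgError):
            valid[i] = False
    fs = FeatureSet(features.targets, out, glints=features.glints,
                    valid=valid, meta=dict(features.meta))
    fs.meta["space"] = "glint-normalized"
    return fs
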