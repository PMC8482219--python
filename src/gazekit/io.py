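"""Reading and writing the annotated eye-tracking CSV schema and reports.

The on-disk record format mirrors public annotated eye-tracking CSV files:
one row per video frame with frame number, target ID, timestamp (ms), viewed
target coordinates, pupil center, fitted pupil-ellipse axes/orientation and
four enumerated corneal-reflection (glint) coordinates.  Missing glints are
blank fields, never zeros.

Dialect: comma-separated, dot decimal, single header row, UTF-8; pixel
coordinates are 0-based with origin at the top-left.  Floats are written
with 6 decimals so that read ∘ write is byte-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import FeatureSet, Scene, calibration_indices, grid_targets, simulate_session

__all__ = [
    "EyeInfoRecord",
    "EYEINFO_COLUMNS",
    "read_eyeinfo",
    "write_eyeinfo",
    "eyeinfo_to_featureset",
    "featureset_to_records",
    "make_fixtures",
]

EYEINFO_COLUMNS = (
    "frame_number",
    "target_id",
    "timestamp",
    "target_x",
    "target_y",
    "pupil_x",
    "pupil_y",
    "ellipse_major",
    "ellipse_minor",
    "ellipse_angle",
    "glint0_x",
    "glint0_y",
    "glint1_x",
    "glint1_y",
    "glint2_x",
    "glint2_y",
    "glint3_x",
    "glint3_y",
)

_INT_COLUMNS = ("frame_number", "target_id")
_GLINT_COLUMNS = tuple(c for c in EYEINFO_COLUMNS if c.startswith("glint"))


@dataclass(frozen=True)
class EyeInfoRecord:
    """One annotated eye-tracking frame."""

    frame_number: int
    target_id: int
    timestamp: float
    target_xy: tuple[float, float]
    pupil_center: tuple[float, float]
    ellipse_major: float = 0.0
    ellipse_minor: float = 0.0
    ellipse_angle: float = 0.0
    glints: tuple[tuple[float, float] | None, ...] = (None, None, None, None)
    extra: dict = field(default_factory=dict)


def read_eyeinfo(path, column_map: dict[str, str] | None = None) -> list[EyeInfoRecord]:
    """Parse an annotated CSV into typed records.

    ``column_map`` renames source columns onto the canonical schema (for
    files whose headers differ).  Blank glint fields parse as missing; a
    malformed value raises with its 1-based data line number; unknown
    columns are preserved per-record in ``extra`` with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in EYEINFO_COLUMNS if c not in df.columns and not c.startswith("glint")]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in EYEINFO_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: unknown columns {unknown} kept as metadata", stacklevel=2)

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = dict(zip(df.columns, row))
        try:
            glints = []
            for g in range(4):
                gx, gy = row.get(f"glint{g}_x", ""), row.get(f"glint{g}_y", "")
                glints.append(None if gx == "" or gy == "" else (float(gx), float(gy)))
            records.append(
                EyeInfoRecord(
                    frame_number=int(row["frame_number"]),
                    target_id=int(row["target_id"]),
                    timestamp=float(row["timestamp"]),
                    target_xy=(float(row["target_x"]), float(row["target_y"])),
                    pupil_center=(float(row["pupil_x"]), float(row["pupil_y"])),
                    ellipse_major=float(row.get("ellipse_major", 0) or 0),
                    ellipse_minor=float(row.get("ellipse_minor", 0) or 0),
                    ellipse_angle=float(row.get("ellipse_angle", 0) or 0),
                    glints=tuple(glints),
                    extra={c: row[c] for c in unknown},
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_eyeinfo(records: list[EyeInfoRecord], path) -> None:
    """Write records in the canonical schema (byte-stable numeric format)."""
    rows = []
    for r in records:
        row = {
            "frame_number": r.frame_number,
            "target_id": r.target_id,
            "timestamp": _fmt(r.timestamp),
            "target_x": _fmt(r.target_xy[0]),
            "target_y": _fmt(r.target_xy[1]),
            "pupil_x": _fmt(r.pupil_center[0]),
            "pupil_y": _fmt(r.pupil_center[1]),
            "ellipse_major": _fmt(r.ellipse_major),
            "ellipse_minor": _fmt(r.ellipse_minor),
            "ellipse_angle": _fmt(r.ellipse_angle),
        }
        for g in range(4):
            gl = r.glints[g] if g < len(r.glints) else None
            row[f"glint{g}_x"] = "" if gl is None else _fmt(gl[0])
            row[f"glint{g}_y"] = "" if gl is None else _fmt(gl[1])
        rows.append(row)
    pd.DataFrame(rows, columns=list(EYEINFO_COLUMNS)).to_csv(path, index=False)


def eyeinfo_to_featureset(records: list[EyeInfoRecord], meta: dict | None = None) -> FeatureSet:
    """Assemble records (one per frame) into the in-memory exchange type."""
    targets = np.array([r.target_xy for r in records], float)
    feats = np.array([r.pupil_center for r in records], float)
    glints = np.full((len(records), 4, 2), np.nan)
    for i, r in enumerate(records):
        for g, gl in enumerate(r.glints):
            if gl is not None:
                glints[i, g] = gl
    return FeatureSet(targets=targets, features=feats, glints=glints, meta=meta or {})


def featureset_to_records(
    fs: FeatureSet,
    samples_per_target: int = 1,
    fps: float = 150.0,
    rng: np.random.Generator | None = None,
    noise_px: float = 0.0,
) -> list[EyeInfoRecord]:
    """Expand a (one-row-per-target) feature set to frame records, optionally
    replicating each target ``samples_per_target`` times with seeded Gaussian
    pixel jitter on the pupil and glints."""
    records = []
    frame = 0
    for i in range(len(fs)):
        for _ in range(samples_per_target):
            pupil = np.asarray(fs.features[i], float)
            glints = fs.glints[i].copy() if fs.glints is not None else None
            if noise_px > 0 and rng is not None:
                pupil = pupil + rng.normal(0.0, noise_px, 2)
                if glints is not None:
                    glints = glints + rng.normal(0.0, noise_px, glints.shape)
            gl_tuple = (None, None, None, None)
            if glints is not None:
                gl_tuple = tuple(
                    None if not np.isfinite(g).all() else (float(g[0]), float(g[1]))
                    for g in glints
                )
            records.append(
                EyeInfoRecord(
                    frame_number=frame,
                    target_id=i,
                    timestamp=frame * 1000.0 / fps,
                    target_xy=(float(fs.targets[i, 0]), float(fs.targets[i, 1])),
                    pupil_center=(float(pupil[0]), float(pupil[1])),
                    glints=gl_tuple,
                )
            )
            frame += 1
    return records


def make_fixtures(outdir, seed: int, samples_per_target: int = 150) -> dict[str, Path]:
    """Generate deterministic annotated-CSV fixture sessions from the
    simulator, emulating the user-study protocol: a 7×5 target grid with a
    3×3 calibration subset and 150 jittered samples per target.

    Three files are produced: a clean session, one with missing glints, and
    one whose pupil trace carries a gross offset (an outlier trial).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scene = _fixture_scene()
    targets = grid_targets(scene.screen, 7, 5)
    fs = simulate_session(scene, targets, with_glints=True)
    fs = _to_pixel_conventions(fs, scene)

    paths = {}
    clean = featureset_to_records(
        fs, samples_per_target=samples_per_target, rng=rng, noise_px=0.002
    )
    paths["clean"] = outdir / "session_clean.csv"
    write_eyeinfo(clean, paths["clean"])

    # missing glints: drop glint #2 on a deterministic subset of frames
    missing = [
        EyeInfoRecord(
            r.frame_number, r.target_id, r.timestamp, r.target_xy, r.pupil_center,
            r.ellipse_major, r.ellipse_minor, r.ellipse_angle,
            (r.glints[0], r.glints[1], None, r.glints[3]) if r.frame_number % 7 == 0 else r.glints,
        )
        for r in featureset_to_records(
            fs, samples_per_target=samples_per_target, rng=rng, noise_px=0.002
        )
    ]
    paths["missing_glints"] = outdir / "session_missing_glints.csv"
    write_eyeinfo(missing, paths["missing_glints"])

    # outlier trial: gross pupil drift after calibration (applied to the
    # non-calibration targets only) => mean gaze error above 5 degrees
    drift = np.zeros_like(fs.features)
    non_calib = np.setdiff1d(np.arange(len(fs)), calibration_indices(7, 5))
    drift[non_calib] = 250.0
    outlier_fs = fs.with_features(fs.features + drift)
    outlier = featureset_to_records(
        outlier_fs, samples_per_target=samples_per_target, rng=rng, noise_px=0.002
    )
    paths["outlier_trial"] = outdir / "session_outlier.csv"
    write_eyeinfo(outlier, paths["outlier_trial"])
    return paths


def _fixture_scene() -> Scene:
    from .simulator import default_scene

    return default_scene(with_leds=True)


#: Image-sensor pixel scale used when exporting simulated sessions in the
#: pixel conventions of real recordings (px per mm of sensor, plus the image
#: center offset of a 1600×1200 sensor).
IMAGE_PX_PER_MM = 100.0
IMAGE_CENTER_PX = (800.0, 600.0)


def _to_pixel_conventions(fs: FeatureSet, scene: Scene) -> FeatureSet:
    """Re-express a simulated session in the units of real recordings:
    targets in screen pixels (origin top-left, y down), pupil and glints in
    image pixels (origin top-left)."""
    pitch = scene.screen.pixel_pitch
    x0 = scene.screen.x_range[0]
    y1 = scene.screen.y_range[1]
    targets_px = np.column_stack(
        [(fs.targets[:, 0] - x0) / pitch, (y1 - fs.targets[:, 1]) / pitch]
    )
    feats_px = fs.features * np.array([1.0, -1.0]) * IMAGE_PX_PER_MM + IMAGE_CENTER_PX
    glints_px = None
    if fs.glints is not None:
        glints_px = fs.glints * np.array([1.0, -1.0]) * IMAGE_PX_PER_MM + IMAGE_CENTER_PX
    return FeatureSet(targets_px, feats_px, glints=glints_px,
                      meta={**fs.meta, "units": "px"})


def fixture_calibration_indices() -> np.ndarray:
    """3×3 calibration subset of the 7×5 fixture target grid (boundary
    targets plus the center)."""
    return calibration_indices(7, 5)


def write_report(report: dict, out_json, out_csv=None) -> None:
    """Persist an evaluation report: JSON summary plus an optional CSV of the
    per-method Gaussian band table."""
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=2)
    if out_csv is not None and "gaussian_band" in report:
        pd.DataFrame(report["gaussian_band"]).T.to_csv(out_csv)
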