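"""Geometric eye-tracker simulator.

Simulates a remote eye-tracking setup: a schematic eye (two-sphere
Gullstrand–Le Grand-style model) placed in front of a screen rotates to
fixate targets, while a pinhole eye-camera images the pupil center (through
corneal refraction) and the corneal reflections (glints) of LEDs mounted at
the screen corners.

World coordinate system: origin at the bottom-center of the screen,
x right, y up, z toward the user; all lengths in millimetres, angles in
degrees unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import geometry as geo

__all__ = [
    "EyeModel",
    "Camera",
    "Screen",
    "Scene",
    "EyeState",
    "FeatureSet",
    "SweepResult",
    "RotationLimitError",
    "gaze_at",
    "observe_pupil",
    "observe_glints",
    "simulate_session",
    "camera_sweep",
    "grid_targets",
    "calibration_indices",
    "default_scene",
]


class RotationLimitError(ValueError):
    """Requested fixation exceeds the oculomotor rotation range."""


@dataclass(frozen=True)
class EyeModel:
    """Schematic eye: two spheres (eyeball + cornea) sharing an optical axis.

    The optical axis passes through the eyeball center ``O_e``, the corneal
    center of curvature ``O_c`` (at ``cornea_center_offset`` mm from ``O_e``)
    and the pupil center ``P_c`` (at ``pupil_distance`` mm from ``O_e``).
    The visual axis deviates from the optical axis by the angle kappa
    ``(kappa_h, kappa_v)``.  The aqueous humor behind the cornea has
    refractive index ``refraction_index``.
    """

    eyeball_center: tuple[float, float, float] = (0.0, 200.0, 550.0)
    eyeball_radius: float = 12.0
    cornea_center_offset: float = 5.3
    cornea_radius: float = 7.8
    pupil_distance: float = 9.2
    kappa: tuple[float, float] = (6.0, 2.0)
    refraction_index: float = 1.336
    # max rotation (degrees): left, right, up, down
    rotation_limits: tuple[float, float, float, float] = (35.0, 35.0, 25.0, 30.0)

    def __post_init__(self):
        if self.refraction_index <= 1.0:
            raise ValueError("refraction_index must exceed 1")
        if min(self.eyeball_radius, self.cornea_radius, self.pupil_distance) <= 0:
            raise ValueError("all radii and distances must be positive")
        if not (
            self.pupil_distance > self.cornea_center_offset - self.cornea_radius
            and abs(self.pupil_distance - self.cornea_center_offset) < self.cornea_radius
        ):
            raise ValueError("pupil center must lie inside the corneal sphere")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.eyeball_center, dtype=float)


@dataclass(frozen=True)
class Camera:
    """Pinhole eye-camera; it looks at the point ``look_at`` (the eyeball
    center by default, matching the usual remote-setup alignment)."""

    position: tuple[float, float, float] = (0.0, 200.0, 0.0)
    look_at: tuple[float, float, float] | None = None
    focal_length: float = 35.0
    principal_point: tuple[float, float] = (0.0, 0.0)

    def frame(self, default_target: np.ndarray) -> np.ndarray:
        target = self.look_at if self.look_at is not None else default_target
        return geo.camera_frame(np.asarray(self.position, float), target)


@dataclass(frozen=True)
class Screen:
    """Viewed plane at z=0.  Targets live in ``x_range`` × ``y_range`` (mm);
    ``pixel_pitch`` converts mm to screen pixels when needed."""

    width: float = 400.0
    height: float = 300.0
    x_range: tuple[float, float] = (-200.0, 200.0)
    y_range: tuple[float, float] = (50.0, 350.0)
    pixel_pitch: float = 0.27675


@dataclass(frozen=True)
class Scene:
    screen: Screen = field(default_factory=Screen)
    camera: Camera = field(default_factory=Camera)
    eye: EyeModel = field(default_factory=EyeModel)
    leds: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if np.allclose(self.camera.position, self.eye.eyeball_center):
            raise ValueError("camera must not coincide with the eyeball center")

    def with_camera_at(self, position) -> "Scene":
        return replace(self, camera=replace(self.camera, position=tuple(position)))

    def to_dict(self) -> dict:
        return {
            "screen": {
                "width": self.screen.width,
                "height": self.screen.height,
                "x_range": list(self.screen.x_range),
                "y_range": list(self.screen.y_range),
                "pixel_pitch": self.screen.pixel_pitch,
            },
            "camera": {
                "position": list(self.camera.position),
                "look_at": None if self.camera.look_at is None else list(self.camera.look_at),
                "focal_length": self.camera.focal_length,
                "principal_point": list(self.camera.principal_point),
            },
            "eye": {
                "eyeball_center": list(self.eye.eyeball_center),
                "eyeball_radius": self.eye.eyeball_radius,
                "cornea_center_offset": self.eye.cornea_center_offset,
                "cornea_radius": self.eye.cornea_radius,
                "pupil_distance": self.eye.pupil_distance,
                "kappa": list(self.eye.kappa),
                "refraction_index": self.eye.refraction_index,
                "rotation_limits": list(self.eye.rotation_limits),
            },
            "leds": [list(l) for l in self.leds],
            "units": {"length": "mm", "angle": "deg"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        s = d.get("screen", {})
        c = d.get("camera", {})
        e = d.get("eye", {})
        screen = Screen(
            width=s.get("width", 400.0),
            height=s.get("height", 300.0),
            x_range=tuple(s.get("x_range", (-200.0, 200.0))),
            y_range=tuple(s.get("y_range", (50.0, 350.0))),
            pixel_pitch=s.get("pixel_pitch", 0.27675),
        )
        camera = Camera(
            position=tuple(c.get("position", (0.0, 200.0, 0.0))),
            look_at=None if c.get("look_at") is None else tuple(c["look_at"]),
            focal_length=c.get("focal_length", 35.0),
            principal_point=tuple(c.get("principal_point", (0.0, 0.0))),
        )
        eye = EyeModel(
            eyeball_center=tuple(e.get("eyeball_center", (0.0, 200.0, 550.0))),
            eyeball_radius=e.get("eyeball_radius", 12.0),
            cornea_center_offset=e.get("cornea_center_offset", 5.3),
            cornea_radius=e.get("cornea_radius", 7.8),
            pupil_distance=e.get("pupil_distance", 9.2),
            kappa=tuple(e.get("kappa", (6.0, 2.0))),
            refraction_index=e.get("refraction_index", 1.336),
            rotation_limits=tuple(e.get("rotation_limits", (35.0, 35.0, 25.0, 30.0))),
        )
        return cls(screen=screen, camera=camera, eye=eye,
                   leds=tuple(tuple(l) for l in d.get("leds", ())))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scene(with_leds: bool = False) -> Scene:
    """The simulated-study scene: eye at (0, 200, 550) mm in front of a
    400×300 mm screen, camera at the screen plane looking at the eye."""
    leds = ()
    if with_leds:
        leds = ((-200.0, 50.0, 0.0), (200.0, 50.0, 0.0),
                (200.0, 350.0, 0.0), (-200.0, 350.0, 0.0))
    return Scene(leds=leds)


@dataclass(frozen=True)
class EyeState:
    """Orientation of the eye while fixating one target."""

    optical_axis: np.ndarray  # unit vector, eye → screen
    visual_axis: np.ndarray
    pupil_center_world: np.ndarray
    cornea_center_world: np.ndarray
    gazed_target: np.ndarray  # (x, y) mm on the screen


def _eye_frame(optical_axis: np.ndarray) -> np.ndarray:
    """Eye-fixed frame rows (right, up, forward=optical axis)."""
    fwd = geo.normalize(np.asarray(optical_axis, float))
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, np.broadcast_to(up, fwd.shape))
    right = geo.normalize(right)
    true_up = np.cross(right, fwd)
    return np.stack([right, true_up, fwd], axis=-2)


def _kappa_direction(kappa: tuple[float, float]) -> np.ndarray:
    """Visual-axis direction in the eye frame (forward = +z): the forward
    vector rotated by kappa_v about the eye's horizontal axis, then kappa_h
    about its vertical axis."""
    ka, kb = np.deg2rad(kappa[0]), np.deg2rad(kappa[1])
    v = np.array([0.0, -np.sin(kb), np.cos(kb)])  # Rx(kappa_v) @ e_z
    ry = np.array(
        [[np.cos(ka), 0.0, np.sin(ka)], [0.0, 1.0, 0.0], [-np.sin(ka), 0.0, np.cos(ka)]]
    )
    return ry @ v


def _gaze_at_many(eye: EyeModel, targets: np.ndarray, check_limits: bool = True):
    """Solve eye orientations for an (n, 2) array of screen targets.

    The visual axis is anchored at the corneal center (nodal point) and must
    pass through the target; since the corneal center itself moves with the
    orientation, the optical axis is found by a fast fixed-point iteration.
    Returns (optical_axes, visual_axes, pupil_centers, cornea_centers).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    t3 = np.column_stack([targets, np.zeros(len(targets))])
    o_e = eye.center
    k_dir = _kappa_direction(eye.kappa)

    omega = geo.normalize(t3 - o_e)  # initial guess: optical toward target
    for _ in range(60):
        frame = _eye_frame(omega)
        v_cur = np.einsum("...ji,j->...i", frame, k_dir)  # eye→world
        o_c = o_e + eye.cornea_center_offset * omega
        v_req = geo.normalize(t3 - o_c)
        err = np.max(np.linalg.norm(v_cur - v_req, axis=-1))
        rot = geo.rotation_between(v_cur, v_req)
        omega = geo.normalize(np.einsum("...ij,...j->...i", rot, omega))
        if err < 1e-14:
            break

    if check_limits:
        # horizontal angle: positive toward +x (viewer's right)
        horiz = np.rad2deg(np.arctan2(omega[:, 0], -omega[:, 2]))
        vert = np.rad2deg(np.arctan2(omega[:, 1], np.hypot(omega[:, 0], omega[:, 2])))
        left, right, up, down = eye.rotation_limits
        if np.any(horiz < -left - 1e-9) or np.any(horiz > right + 1e-9):
            raise RotationLimitError(
                f"horizontal rotation {float(np.max(np.abs(horiz))):.2f} deg exceeds "
                f"the ({left} left / {right} right) deg limit"
            )
        if np.any(vert > up + 1e-9) or np.any(vert < -down - 1e-9):
            raise RotationLimitError(
                f"vertical rotation {float(np.max(np.abs(vert))):.2f} deg exceeds "
                f"the ({up} up / {down} down) deg limit"
            )

    frame = _eye_frame(omega)
    visual = np.einsum("...ji,j->...i", frame, k_dir)
    pupil = o_e + eye.pupil_distance * omega
    cornea = o_e + eye.cornea_center_offset * omega
    return omega, visual, pupil, cornea


def gaze_at(eye: EyeModel, target) -> EyeState:
    """Rotate ``eye`` so its visual axis fixates ``target`` (x, y) on the
    screen plane z=0.

    Raises :class:`RotationLimitError` when the required rotation exceeds the
    model's oculomotor range, naming the offending axis.
    """
    target = np.asarray(target, dtype=float)
    omega, visual, pupil, cornea = _gaze_at_many(eye, target[None, :])
    return EyeState(
        optical_axis=omega[0],
        visual_axis=visual[0],
        pupil_center_world=pupil[0],
        cornea_center_world=cornea[0],
        gazed_target=target,
    )


def observe_pupil(state: EyeState, scene: Scene, refraction: bool = True) -> np.ndarray:
    """Image coordinates of the pupil center seen by the scene's camera.

    With ``refraction`` the camera sees the virtual pupil image: the ray
    camera → cornea refracts at the corneal sphere (Snell's law, air to
    aqueous humor) and must pass through the true pupil center; the imaged
    point is the refraction point on the cornea.
    """
    cam_pos = np.asarray(scene.camera.position, float)
    R = scene.camera.frame(scene.eye.center)
    if refraction:
        x = geo.refraction_point(
            cam_pos,
            state.cornea_center_world,
            scene.eye.cornea_radius,
            state.pupil_center_world,
            scene.eye.refraction_index,
        )[0]
    else:
        x = state.pupil_center_world
    return geo.pinhole_project(
        x, cam_pos, R, scene.camera.focal_length, scene.camera.principal_point
    )


def observe_glints(state: EyeState, scene: Scene) -> np.ndarray:
    """Image coordinates of the corneal reflections of the scene's LEDs,
    in LED order; rows are NaN where no reflection is visible."""
    if len(scene.leds) == 0:
        raise ValueError("scene has no LEDs configured")
    cam_pos = np.asarray(scene.camera.position, float)
    R = scene.camera.frame(scene.eye.center)
    out = np.full((len(scene.leds), 2), np.nan)
    for i, led in enumerate(scene.leds):
        try:
            x = geo.reflection_point(
                cam_pos, state.cornea_center_world, scene.eye.cornea_radius,
                np.asarray(led, float),
            )[0]
            out[i] = geo.pinhole_project(
                x, cam_pos, R, scene.camera.focal_length, scene.camera.principal_point
            )
        except geo.GeometryError:
            pass  # marked missing
    return out


@dataclass
class FeatureSet:
    """Corresponded (target, eye feature, glints) records for one session.

    The universal exchange container: the simulator writes it, the
    compensation/undistortion/mapping stages transform the ``features``
    column, and the evaluation consumes it.
    """

    targets: np.ndarray          # (n, 2) screen mm (or px for real data)
    features: np.ndarray         # (n, 2) eye-image coordinates
    glints: np.ndarray | None = None   # (n, 4, 2), NaN = missing
    valid: np.ndarray | None = None    # (n,) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if len(self.targets) != len(self.features):
            raise ValueError("targets and features must pair up")
        if self.valid is None:
            self.valid = np.isfinite(self.features).all(axis=1)

    def __len__(self) -> int:
        return len(self.targets)

    def with_features(self, features: np.ndarray) -> "FeatureSet":
        return FeatureSet(self.targets, np.asarray(features, float),
                          glints=self.glints, valid=self.valid.copy(),
                          meta=dict(self.meta))


def grid_targets(screen: Screen, nx: int, ny: int) -> np.ndarray:
    """Row-major (nx*ny, 2) grid of targets spanning the screen's target
    range, top row first (reading order)."""
    xs = np.linspace(screen.x_range[0], screen.x_range[1], nx)
    ys = np.linspace(screen.y_range[1], screen.y_range[0], ny)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def calibration_indices(nx: int, ny: int) -> np.ndarray:
    """Row-major indices of the 3×3 calibration subset (corners, edge
    midpoints, center) of an ``nx`` × ``ny`` target grid."""
    if nx < 3 or ny < 3 or (nx - 1) % 2 or (ny - 1) % 2:
        raise ValueError("grid must be odd-sized and at least 3x3")
    cols = [0, (nx - 1) // 2, nx - 1]
    rows = [0, (ny - 1) // 2, ny - 1]
    return np.array([r * nx + c for r in rows for c in cols])


def simulate_session(
    scene: Scene,
    targets: np.ndarray | tuple[int, int] = (21, 21),
    refraction: bool = True,
    with_glints: bool = False,
) -> FeatureSet:
    """Deterministically simulate one eye-tracking session: the eye fixates
    every target in row-major order while the camera records the pupil
    feature (and optionally the four glints)."""
    if isinstance(targets, tuple):
        targets = grid_targets(scene.screen, *targets)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    omega, visual, pupil, cornea = _gaze_at_many(scene.eye, targets)
    cam_pos = np.asarray(scene.camera.position, float)
    R = scene.camera.frame(scene.eye.center)
    if refraction:
        pts = geo.refraction_point(
            cam_pos, cornea, scene.eye.cornea_radius, pupil,
            scene.eye.refraction_index,
        )
    else:
        pts = pupil
    feats = geo.pinhole_project(
        pts, cam_pos, R, scene.camera.focal_length, scene.camera.principal_point
    )
    glints = None
    if with_glints:
        glints = np.empty((len(targets), len(scene.leds), 2))
        for i in range(len(targets)):
            st = EyeState(omega[i], visual[i], pupil[i], cornea[i], targets[i])
            glints[i] = observe_glints(st, scene)
    return FeatureSet(
        targets=targets,
        features=feats,
        glints=glints,
        meta={
            "camera_position": tuple(cam_pos),
            "refraction": refraction,
            "scene": scene.to_dict(),
        },
    )


@dataclass
class SweepResult:
    """Feature sets for every camera position of a 3-D sweep."""

    positions: np.ndarray              # (m, 3) camera positions
    grid_shape: tuple[int, int, int]   # (nx, ny, nz)
    feature_sets: list[FeatureSet]
    calibration_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def sweep_positions(
    x_range=(-200.0, 200.0, 21),
    y_range=(50.0, 350.0, 21),
    z_range=(0.0, 400.0, 21),
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Uniform camera grid; each range is (lo, hi, count)."""
    xs = np.linspace(*x_range)
    ys = np.linspace(*y_range)
    zs = np.linspace(*z_range)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]), (len(xs), len(ys), len(zs))


def camera_sweep(
    scene: Scene,
    x_range=(-200.0, 200.0, 21),
    y_range=(50.0, 350.0, 21),
    z_range=(0.0, 400.0, 21),
    targets: tuple[int, int] = (21, 21),
    refraction: bool = True,
) -> SweepResult:
    """Simulate one session per camera position on a uniform 3-D grid.

    The eye/target protocol is identical at every position, so the eye poses
    are solved once and only the camera observation is repeated.
    """
    positions, shape = sweep_positions(x_range, y_range, z_range)
    tgrid = grid_targets(scene.screen, *targets)
    feats = batch_observe(scene, positions, tgrid, refraction=refraction)
    sets = []
    for pos, f in zip(positions, feats):
        sets.append(
            FeatureSet(
                targets=tgrid,
                features=f,
                meta={"camera_position": tuple(pos), "refraction": refraction},
            )
        )
    return SweepResult(
        positions=positions,
        grid_shape=shape,
        feature_sets=sets,
        calibration_indices=calibration_indices(*targets),
    )


def batch_observe(
    scene: Scene,
    camera_positions: np.ndarray,
    targets: np.ndarray,
    refraction: bool = True,
    chunk: int = 32,
) -> np.ndarray:
    """Pupil features for every (camera position, target) pair.

    The eye poses depend only on the targets, so they are solved once; the
    refraction solve and projection are then evaluated in camera chunks fully
    vectorized.  Returns an (m, n, 2) array for m cameras and n targets.
    """
    camera_positions = np.atleast_2d(np.asarray(camera_positions, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    _, _, pupil, cornea = _gaze_at_many(scene.eye, targets)
    m, n = len(camera_positions), len(targets)
    out = np.empty((m, n, 2))
    for start in range(0, m, chunk):
        cams = camera_positions[start : start + chunk]  # (c, 3)
        R = geo.look_at_frame(scene.eye.center - cams)  # (c, 3, 3)
        if refraction:
            pts = geo.refraction_point(
                cams[:, None, :],
                cornea[None, :, :],
                scene.eye.cornea_radius,
                pupil[None, :, :],
                scene.eye.refraction_index,
            )  # (c, n, 3)
        else:
            pts = np.broadcast_to(pupil[None, :, :], (len(cams), n, 3))
        rel = pts - cams[:, None, :]
        cam_xyz = np.einsum("cij,cnj->cni", R, rel)
        uv = scene.camera.focal_length * cam_xyz[..., :2] / cam_xyz[..., 2:3]
        out[start : start + chunk] = uv + np.asarray(scene.camera.principal_point)
    return out
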