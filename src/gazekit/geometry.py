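"""Vectorized 3-D geometry primitives for eye-tracker simulation.

All positions are in millimetres in a world coordinate system anchored at the
bottom-center of the viewed plane (screen), with x to the viewer's right,
y up, and z pointing from the screen toward the user.  Every routine accepts
and returns plain ``numpy`` arrays and broadcasts over leading axes so that a
full camera-position sweep can be evaluated without Python-level loops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "rotation_from_axis_angle",
    "rotation_between",
    "look_at_frame",
    "camera_frame",
    "pinhole_project",
    "refract_ray",
    "refraction_point",
    "reflection_point",
    "GeometryError",
]


class GeometryError(RuntimeError):
    """Raised when a geometric solve has no valid solution."""


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Return ``v`` scaled to unit length along ``axis``."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def rotation_from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, broadcasting over leading axes.

    Parameters
    ----------
    axis : (..., 3) unit vectors
    angle : (...,) radians
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    x, y, z = axis[..., 0], axis[..., 1], axis[..., 2]
    zero = np.zeros_like(x)
    K = np.stack(
        [
            np.stack([zero, -z, y], axis=-1),
            np.stack([z, zero, -x], axis=-1),
            np.stack([-y, x, zero], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), K.shape)
    s = np.sin(angle)[..., None, None]
    c = np.cos(angle)[..., None, None]
    return eye + s * K + (1.0 - c) * (K @ K)


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vectors ``a`` onto unit vectors ``b``.

    For (anti-)parallel inputs the identity is returned for the parallel case;
    the antiparallel case (undefined axis) is not needed by the simulator and
    raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cross = np.cross(a, b)
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    sin = np.linalg.norm(cross, axis=-1)
    if np.any(dot < -1.0 + 1e-12):
        raise GeometryError("rotation_between undefined for antiparallel vectors")
    angle = np.arctan2(sin, dot)
    small = sin < 1e-15
    axis = np.where(small[..., None], np.array([1.0, 0.0, 0.0]), cross)
    axis = normalize(axis)
    angle = np.where(small, 0.0, angle)
    return rotation_from_axis_angle(axis, angle)


def look_at_frame(forward: np.ndarray, up: np.ndarray | None = None) -> np.ndarray:
    """Right-handed orthonormal frame with rows (right, up, forward).

    ``forward`` is the viewing direction; the world up hint defaults to +y.
    Broadcasts over leading axes; returns (..., 3, 3) matrices whose rows are
    the frame axes expressed in world coordinates.
    """
    f = normalize(np.asarray(forward, dtype=float))
    if up is None:
        up = np.array([0.0, 1.0, 0.0])
    up = np.broadcast_to(np.asarray(up, dtype=float), f.shape)
    right = np.cross(up, f)
    norm = np.linalg.norm(right, axis=-1)
    if np.any(norm < 1e-12):
        raise GeometryError("viewing direction parallel to the up hint")
    right = right / norm[..., None]
    true_up = np.cross(f, right)
    return np.stack([right, true_up, f], axis=-2)


def camera_frame(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Frame of a camera at ``position`` looking at ``target`` (rows R of
    world→camera rotation)."""
    return look_at_frame(np.asarray(target, float) - np.asarray(position, float))


def pinhole_project(
    points: np.ndarray,
    position: np.ndarray,
    rotation: np.ndarray,
    focal_length: float,
    principal_point: np.ndarray | None = None,
) -> np.ndarray:
    """Project world ``points`` (..., 3) with a pinhole camera.

    ``rotation`` holds the world→camera rows from :func:`camera_frame`;
    image coordinates come out in the same length unit as ``focal_length``
    (millimetres on the virtual sensor), origin at the principal point.
    """
    rel = np.asarray(points, float) - np.asarray(position, float)
    cam = np.einsum("...ij,...j->...i", rotation, rel)
    z = cam[..., 2]
    if np.any(z <= 0):
        raise GeometryError("point behind the camera")
    uv = focal_length * cam[..., :2] / z[..., None]
    if principal_point is not None:
        uv = uv + np.asarray(principal_point, float)
    return uv


def refract_ray(d: np.ndarray, n: np.ndarray, eta: float) -> np.ndarray:
    """Snell refraction of unit directions ``d`` at surface normals ``n``.

    ``eta`` is the ratio n1/n2 of refractive indices (incident/transmitted);
    ``n`` must oppose ``d`` (point toward the incident side).
    """
    cos_i = -np.sum(d * n, axis=-1)
    disc = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if np.any(disc < 0):
        raise GeometryError("total internal reflection")
    return eta * d + (eta * cos_i - np.sqrt(disc))[..., None] * n


def _plane_basis(center, toward_u, toward_w):
    """Orthonormal in-plane basis (u, w) around ``center``: u toward the first
    point, w the orthogonal component toward the second."""
    a = np.asarray(toward_u, float) - center
    u = normalize(a)
    b = np.asarray(toward_w, float) - center
    b_perp = b - np.sum(b * u, axis=-1, keepdims=True) * u
    norm = np.linalg.norm(b_perp, axis=-1, keepdims=True)
    # Degenerate (collinear) case: any orthonormal completion works, and the
    # solver then returns theta = 0.
    fallback = np.cross(u, np.array([1.0, 0.0, 0.0]))
    bad = np.linalg.norm(fallback, axis=-1, keepdims=True) < 1e-9
    fallback = np.where(bad, np.cross(u, np.array([0.0, 1.0, 0.0])), fallback)
    w = np.where(norm < 1e-12, normalize(fallback), b_perp / np.where(norm == 0, 1.0, norm))
    return u, w


def _bisect_on_arc(f, lo, hi, iters: int = 80):
    """Vectorized bisection of ``f`` over angle brackets [lo, hi]."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_lo = np.sign(fm) == np.sign(flo)
        lo = np.where(take_lo, mid, lo)
        flo = np.where(take_lo, fm, flo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def refraction_point(
    camera: np.ndarray,
    sphere_center: np.ndarray,
    sphere_radius: float,
    inner_point: np.ndarray,
    refraction_index: float,
) -> np.ndarray:
    """Point on the corneal sphere where the camera ray refracts to hit an
    interior point (the pupil center).

    A ray from ``camera`` refracts into the sphere (air → medium of index
    ``refraction_index``) and must pass through ``inner_point``.  By Snell
    coplanarity the solution lies in the plane spanned by the camera, sphere
    center and inner point, reducing the solve to one angle, found by
    bracketed bisection to well below 1e-9 mm.

    All arguments broadcast; returns points of shape ``broadcast(...) + (3,)``.
    """
    center = np.asarray(sphere_center, float)
    camera = np.asarray(camera, float)
    inner = np.asarray(inner_point, float)
    center, camera, inner = np.broadcast_arrays(
        *(np.atleast_2d(x) if x.ndim == 1 else x for x in (center, camera, inner))
    )
    u, w = _plane_basis(center, camera, inner)
    eta = 1.0 / refraction_index
    b = inner - center
    p_u = np.sum(b * u, axis=-1)
    p_w = np.sum(b * w, axis=-1)

    def residual(theta):
        x = center + sphere_radius * (
            np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * w
        )
        d = normalize(x - camera)
        n = (x - center) / sphere_radius
        t = refract_ray(d, n, eta)
        v = inner - x
        t_u = np.sum(t * u, axis=-1)
        t_w = np.sum(t * w, axis=-1)
        v_u = np.sum(v * u, axis=-1)
        v_w = np.sum(v * w, axis=-1)
        return t_u * v_w - t_w * v_u

    lo = np.zeros(p_u.shape)
    theta_b = np.arctan2(np.abs(p_w), p_u)
    hi = np.clip(theta_b, 1e-6, 0.5 * np.pi)
    # Expand the bracket until the residual changes sign (grazing geometry).
    f_lo = residual(lo)
    for _ in range(8):
        f_hi = residual(hi)
        bad = (np.sign(f_hi) == np.sign(f_lo)) & (np.abs(f_lo) > 0) & (np.abs(f_hi) > 0)
        if not np.any(bad):
            break
        hi = np.where(bad, np.minimum(hi + 0.25, 0.5 * np.pi + 0.3), hi)
    else:
        raise GeometryError("no refraction solution found (grazing geometry?)")
    theta = _bisect_on_arc(residual, lo, hi)
    return center + sphere_radius * (
        np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * w
    )


def reflection_point(
    camera: np.ndarray,
    sphere_center: np.ndarray,
    sphere_radius: float,
    source: np.ndarray,
) -> np.ndarray:
    """Specular reflection point of a point light ``source`` toward the camera
    on a spherical mirror (the cornea) — the classic Alhazen problem.

    Solved by bisection on the arc between the camera and source directions in
    the plane through camera, sphere center and source.
    """
    center = np.asarray(sphere_center, float)
    camera = np.asarray(camera, float)
    source = np.asarray(source, float)
    center, camera, source = np.broadcast_arrays(
        *(np.atleast_2d(x) if x.ndim == 1 else x for x in (center, camera, source))
    )
    u, w = _plane_basis(center, camera, source)
    b = source - center
    p_u = np.sum(b * u, axis=-1)
    p_w = np.sum(b * w, axis=-1)

    def residual(theta):
        x = center + sphere_radius * (
            np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * w
        )
        n = (x - center) / sphere_radius
        d = normalize(x - source)  # incident direction
        r = d - 2.0 * np.sum(d * n, axis=-1, keepdims=True) * n  # reflected
        v = camera - x
        r_u = np.sum(r * u, axis=-1)
        r_w = np.sum(r * w, axis=-1)
        v_u = np.sum(v * u, axis=-1)
        v_w = np.sum(v * w, axis=-1)
        return r_u * v_w - r_w * v_u

    lo = np.zeros(p_u.shape)
    hi = np.clip(np.arctan2(np.abs(p_w), p_u), 1e-9, np.pi - 1e-6)
    f_lo = residual(lo)
    f_hi = residual(hi)
    if np.any((np.sign(f_lo) == np.sign(f_hi)) & (np.abs(f_lo) > 1e-15) & (np.abs(f_hi) > 1e-15)):
        raise GeometryError("no specular reflection solution on the visible cap")
    theta = _bisect_on_arc(residual, lo, hi)
    return center + sphere_radius * (
        np.cos(theta)[..., None] * u + np.sin(theta)[..., None] * w
    )
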