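"""Coordinate frames, rotation math, interpolation and path-length primitives.

Conventions used throughout the package:

* World frame: right-handed, the x-y plane is the floor, z points up,
  units are meters.  The origin sits at the arena corner nearest the
  curtain; the exact anchor is irrelevant as long as it is fixed.
* Quaternions are stored as ``(w, x, y, z)`` with the canonical sign
  ``w >= 0`` (``q`` and ``-q`` encode the same rotation).
* The head frame has +x pointing "straight ahead": a gaze direction of
  ``(1, 0, 0)`` in the head frame of an identity-oriented head is the
  world direction ``(1, 0, 0)``.
* Angles handed to and returned from public functions are degrees;
  timestamps are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Pose6DOF",
    "Ray",
    "unit",
    "angle_between_deg",
    "quat_normalize",
    "quat_canonical",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_rotate_inverse",
    "quat_from_axis_angle",
    "quat_from_yaw",
    "quat_slerp",
    "quat_slerp_many",
    "random_unit_quaternion",
    "angular_difference",
    "angular_velocity_series",
    "slerp_pose",
    "path_length",
]

_UNIT_TOL = 1e-9


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise InvalidInputError(f"{name} must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return a


def unit(v, name: str = "vector") -> np.ndarray:
    """Return ``v`` scaled to unit norm; reject zero or non-finite input."""
    a = _as_vec3(v, name)
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise InvalidInputError(f"{name} has (near-)zero norm")
    return a / n


def angle_between_deg(a, b) -> float:
    """Angle in degrees between two direction vectors (any positive norm)."""
    ua, ub = unit(a, "a"), unit(b, "b")
    d = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    return float(np.degrees(np.arccos(d)))


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z)
# ---------------------------------------------------------------------------

def _as_quat(q, name: str = "quaternion") -> np.ndarray:
    a = np.asarray(q, dtype=float)
    if a.shape != (4,):
        raise InvalidInputError(f"{name} must have shape (4,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return a


def _require_unit_quat(q, name: str = "quaternion", tol: float = 1e-6) -> np.ndarray:
    a = _as_quat(q, name)
    n = float(np.linalg.norm(a))
    if abs(n - 1.0) > tol:
        raise InvalidInputError(f"{name} is not unit norm (|q| = {n:.9f})")
    return a / n


def quat_normalize(q) -> np.ndarray:
    a = _as_quat(q)
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise InvalidInputError("cannot normalize a zero quaternion")
    return a / n


def quat_canonical(q) -> np.ndarray:
    """Normalize and flip sign so that w >= 0 (w == 0: first non-zero > 0)."""
    a = quat_normalize(q)
    if a[0] < 0:
        return -a
    if a[0] == 0:
        nz = np.nonzero(a)[0]
        if nz.size and a[nz[0]] < 0:
            return -a
    return a


def quat_multiply(q1, q2) -> np.ndarray:
    """Hamilton product q1 * q2 (apply q2 first, then q1)."""
    w1, x1, y1, z1 = _as_quat(q1)
    w2, x2, y2, z2 = _as_quat(q2)
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    a = _as_quat(q)
    return np.array([a[0], -a[1], -a[2], -a[3]])


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q``.

    Accepts a single quaternion with a single vector or (N, 3) vectors, or
    matched (N, 4) / (N, 3) arrays.
    """
    qa = np.atleast_2d(np.asarray(q, dtype=float))
    va = np.atleast_2d(np.asarray(v, dtype=float))
    w = qa[:, :1]
    u = qa[:, 1:]
    if qa.shape[0] == 1 and va.shape[0] > 1:
        w = np.broadcast_to(w, (va.shape[0], 1))
        u = np.broadcast_to(u, (va.shape[0], 3))
    # Rodrigues form: v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, va)
    out = va + 2.0 * w * uv + 2.0 * np.cross(u, uv)
    if np.asarray(v).ndim == 1 and np.asarray(q).ndim == 1:
        return out[0]
    return out


def quat_rotate_inverse(q, v) -> np.ndarray:
    qa = np.atleast_2d(np.asarray(q, dtype=float)).copy()
    qa[:, 1:] *= -1.0
    if np.asarray(q).ndim == 1:
        qa = qa[0]
    return quat_rotate(qa, v)


def quat_from_axis_angle(axis, angle_deg: float) -> np.ndarray:
    ax = unit(axis, "axis")
    half = 0.5 * np.radians(angle_deg)
    return quat_canonical(np.concatenate([[np.cos(half)], np.sin(half) * ax]))


def quat_from_yaw(yaw_deg: float) -> np.ndarray:
    """Rotation about world z by ``yaw_deg`` (heading in the floor plane)."""
    return quat_from_axis_angle((0.0, 0.0, 1.0), yaw_deg)


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    while np.linalg.norm(q) < 1e-6:  # pragma: no cover - astronomically rare
        q = rng.normal(size=4)
    return quat_canonical(q)


def quat_angle_deg(q) -> float:
    """Rotation angle of a unit quaternion, in [0, 180] degrees."""
    a = quat_normalize(q)
    return float(np.degrees(2.0 * np.arctan2(np.linalg.norm(a[1:]), abs(a[0]))))


def angular_difference(q1, q2) -> float:
    """Geodesic angle in degrees between two rotations, in [0, 180].

    Symmetric in its arguments; raises ``InvalidInputError`` for non-unit
    input.
    """
    a = _require_unit_quat(q1, "q1")
    b = _require_unit_quat(q2, "q2")
    return quat_angle_deg(quat_multiply(a, quat_conjugate(b)))


def quat_slerp(q0, q1, u: float) -> np.ndarray:
    """Geodesic interpolation along the shorter arc; u in [0, 1]."""
    return quat_slerp_many(np.asarray(q0)[None], np.asarray(q1)[None], np.array([u]))[0]


def quat_slerp_many(q0, q1, u) -> np.ndarray:
    """Vectorized slerp: (N,4) x (N,4) x (N,) -> (N,4), shorter arc."""
    a = np.atleast_2d(np.asarray(q0, dtype=float))
    b = np.atleast_2d(np.asarray(q1, dtype=float)).copy()
    uu = np.asarray(u, dtype=float).reshape(-1, 1)
    dot = np.sum(a * b, axis=1, keepdims=True)
    b[dot[:, 0] < 0] *= -1.0
    dot = np.abs(np.clip(dot, -1.0, 1.0))
    theta = np.arccos(dot)
    small = theta[:, 0] < 1e-8
    out = np.empty_like(a)
    if np.any(small):
        lerp = (1.0 - uu[small]) * a[small] + uu[small] * b[small]
        out[small] = lerp / np.linalg.norm(lerp, axis=1, keepdims=True)
    big = ~small
    if np.any(big):
        th = theta[big]
        s = np.sin(th)
        out[big] = (np.sin((1.0 - uu[big]) * th) * a[big] + np.sin(uu[big] * th) * b[big]) / s
    return out


# ---------------------------------------------------------------------------
# poses and rays
# ---------------------------------------------------------------------------

@dataclass
class Pose6DOF:
    """Rigid 6-DOF state: timestamp, world position, orientation quaternion."""

    t: float
    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise InvalidInputError(f"pose timestamp must be finite and >= 0, got {self.t}")
        self.position = _as_vec3(self.position, "position")
        self.orientation = quat_canonical(_require_unit_quat(self.orientation, "orientation"))


@dataclass
class Ray:
    """World-frame ray: origin in meters, unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = unit(self.direction, "direction")


def slerp_pose(p0: Pose6DOF, p1: Pose6DOF, u: float) -> Pose6DOF:
    """Interpolate between two timestamped poses.

    Position is interpolated linearly, orientation geodesically along the
    shorter arc.  ``u = 0`` returns ``p0`` exactly, ``u = 1`` returns ``p1``.
    """
    if not np.isfinite(u):
        raise InvalidInputError("interpolation fraction must be finite")
    if not (0.0 <= u <= 1.0):
        raise InvalidInputError(f"interpolation fraction must be in [0, 1], got {u}")
    if not p0.t < p1.t:
        raise InvalidInputError("p0.t must precede p1.t")
    pos = (1.0 - u) * p0.position + u * p1.position
    quat = quat_slerp(p0.orientation, p1.orientation, u)
    return Pose6DOF(t=(1.0 - u) * p0.t + u * p1.t, position=pos, orientation=quat)


# ---------------------------------------------------------------------------
# kinematic series
# ---------------------------------------------------------------------------

def directions_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise angle in degrees between two (N, 3) unit-direction arrays."""
    d = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(d))


def angular_velocity_series(dirs, ts) -> np.ndarray:
    """Per-sample angular speed (deg/s) of a direction trace.

    Interior samples use the central difference (angle between the two
    neighbouring directions over their time separation); the first and last
    sample use the one-sided difference.
    """
    d = np.asarray(dirs, dtype=float)
    t = np.asarray(ts, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] != t.shape[0]:
        raise InvalidInputError("dirs must be (N, 3) matching len(ts)")
    if d.shape[0] < 2:
        raise InvalidInputError("need at least two samples")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timestamps must be strictly increasing (no duplicates)")
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidInputError("directions must be unit vectors")
    v = np.empty(d.shape[0])
    if d.shape[0] > 2:
        v[1:-1] = directions_angle_deg(d[:-2], d[2:]) / (t[2:] - t[:-2])
    v[0] = directions_angle_deg(d[0][None], d[1][None])[0] / (t[1] - t[0])
    v[-1] = directions_angle_deg(d[-2][None], d[-1][None])[0] / (t[-1] - t[-2])
    return v


def path_length(positions, min_step: float = 0.0) -> float:
    """Anchored path integration over a position trace.

    Displacement is accumulated from the last *anchor*; once it reaches
    ``min_step`` the straight-line displacement is added to the total and
    the anchor moves to the current sample.  ``min_step = 0`` reduces to
    the naive polyline sum.  The threshold suppresses the spurious length
    that integrating tracker noise sample-by-sample would contribute.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise InvalidInputError("positions must be a non-empty (N, 3) array")
    if not np.all(np.isfinite(p)):
        raise InvalidInputError("positions contain non-finite values")
    if min_step < 0:
        raise InvalidInputError("min_step must be >= 0")
    if p.shape[0] == 1:
        return 0.0
    if min_step == 0.0:
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    total = 0.0
    anchor = p[0]
    for row in p[1:]:
        dx = row[0] - anchor[0]
        dy = row[1] - anchor[1]
        dz = row[2] - anchor[2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d >= min_step:
            total += d
            anchor = row
    return total
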