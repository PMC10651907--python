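"""Synthetic experiment generator with complete ground truth.

The simulator emulates one session of the 3D same-different task at the
statistical level the downstream pipeline cares about, without modelling
biomechanics: an agent starts at its assigned start position facing away
from the stimuli, turns, walks to a vantage point, and then inspects the
two posted objects through an itinerary of fixation *groups* (several
fixations on one object before switching to the other), with occasional
environment glances and relocations to new vantage points.  It emits

* a 120 Hz head-pose stream and a 50 Hz head-frame gaze stream in the
  formats of :mod:`activegaze.streams`,
* the posed stimulus pair, and
* a ground-truth manifest with every scheduled fixation interval and
  label, the true head path length, and the true answer.

Design of the kinematics
------------------------
Gaze is constructed directly on the 50 Hz sample grid.  During a
scheduled fixation the world gaze direction is constant (the head is
stationary), so its angular velocity is zero.  Transitions between
fixations (saccades, and scanning sweeps during walks) are emitted as
geodesic arcs whose per-sample angular steps lie between ~0.65 deg and
8 deg, i.e. central-difference velocities between ~33 deg/s and
400 deg/s — always above the 30 deg/s fixation threshold, while the
samples adjacent to a fixation stay within 1.2 deg of it and therefore
below threshold.  Consecutive fixation targets are kept at least 2.4 deg
apart.  With noise disabled the I-VT detector therefore recovers the
scheduled events *exactly*, which is what makes the generator usable as
an end-to-end oracle.

Head position and orientation change only inside dedicated motion
intervals whose endpoints lie on the 0.1 s grid shared by the 120 Hz and
50 Hz clocks, with linear/geodesic interpolation inside.  Piecewise
pose interpolation at gaze timestamps is then exact, so synchronization
introduces no kinematic error.

Sensor noise
------------
Gaze error is dominated by a slowly varying calibration offset, modelled
as an AR(1) process (correlation time ~1.5 s) on two tangential
components plus a small white jitter; the stationary mean angular error
is calibrated to the tracker's reported 1.42 deg mean accuracy.  Head
position noise is white and isotropic with 0.2 mm 3D RMSE.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import GenerationError, InvalidInputError
from .geometry import (
    quat_from_yaw,
    quat_rotate,
    quat_rotate_inverse,
    quat_slerp_many,
    unit,
)
from .metrics import COMPLEXITIES, ORIENTATION_LEVELS, START_POSITIONS, TrialRecord
from .stimuli import ObjectInstance, instance_to_dict, make_stimulus_pair
from .streams import GazeStream, HeadStream, write_gaze_csv, write_head_csv, write_trial_json

__all__ = [
    "ArenaLayout",
    "NoiseParams",
    "BehaviorParams",
    "GroundTruth",
    "TrialSim",
    "generate_design",
    "simulate_trial",
    "simulate_experiment",
]

log = logging.getLogger(__name__)

DT_GAZE = 0.02  # 50 Hz
DT_HEAD = 1.0 / 120.0  # 120 Hz
MOTION_GRID = 0.1  # common multiple of both sample periods
STEP_DEG = 0.9  # nominal transition step per gaze sample (45 deg/s)
MAX_STEP_DEG = 8.0  # fastest mid-saccade step (400 deg/s)
MIN_SACCADE_DEG = 2.4  # smallest scheduled saccade amplitude


@dataclass
class ArenaLayout:
    """Arena geometry: 3.4 m x 4.3 m floor, two stimulus posts, start marks.

    Start positions (configurable; only the topology is fixed):
    P_s in line with both posts 1 m behind them, P_l on the perpendicular
    bisector 2.5 m from the inter-object midpoint, P_c oblique at 45 deg,
    2.2 m out.
    """

    width_x: float = 3.4
    depth_y: float = 4.3
    post_positions: tuple = ((1.5, 2.8, 1.2), (1.9, 2.8, 1.2))
    eye_height: float = 1.6
    margin: float = 0.25

    def post_array(self) -> np.ndarray:
        return np.asarray(self.post_positions, dtype=float)

    def objects_midpoint(self) -> np.ndarray:
        return self.post_array().mean(axis=0)

    def start_position(self, name: str) -> np.ndarray:
        posts = self.post_array()
        mid = posts.mean(axis=0)
        axis = unit(posts[1] - posts[0])
        perp = np.array([-axis[1], axis[0], 0.0])
        if np.dot(perp, np.array([0.0, -1.0, 0.0])) < 0:
            perp = -perp  # point away from the posts, toward the curtain side
        if name == "P_s":
            p = posts[0] - axis * 1.0
        elif name == "P_l":
            p = mid + perp * 2.5
        elif name == "P_c":
            p = mid + unit(perp - axis) * 2.2
        else:
            raise InvalidInputError(f"unknown start position {name!r}")
        return np.array([p[0], p[1], self.eye_height])

    def contains(self, xy: np.ndarray, margin: float | None = None) -> bool:
        m = self.margin if margin is None else margin
        return bool(
            (xy[0] >= m) and (xy[0] <= self.width_x - m)
            and (xy[1] >= m) and (xy[1] <= self.depth_y - m)
        )


@dataclass
class NoiseParams:
    """Sensor noise model (see module docstring)."""

    enabled: bool = True
    gaze_mean_error_deg: float = 1.42
    gaze_ar_tau_s: float = 1.5
    gaze_jitter_rms_deg: float = 0.10
    head_rmse_m: float = 0.0002

    def gaze_ar_sigma_deg(self) -> float:
        """Per-component AR(1) std so the total mean angular error is met."""
        total_comp = self.gaze_mean_error_deg / math.sqrt(math.pi / 2.0)
        jitter_comp = self.gaze_jitter_rms_deg / math.sqrt(2.0)
        var = total_comp**2 - jitter_comp**2
        if var <= 0:
            raise InvalidInputError("jitter exceeds the total gaze error budget")
        return math.sqrt(var)


#: grouping-size distribution over run lengths 1..8 and ">8"; the default
#: probabilities are study-level aggregate shares used as simulator
#: calibration (they are inputs, never recovery evidence).  The published
#: shares carry rounding error, so they are renormalized to sum to 1.
_RAW_GROUPING_SHARES = (18.70, 18.43, 12.26, 8.57, 6.71, 4.87, 3.74, 3.23, 18.41)
DEFAULT_GROUPING_PROBS = tuple(s / sum(_RAW_GROUPING_SHARES) for s in _RAW_GROUPING_SHARES)


@dataclass
class BehaviorParams:
    """Agent behaviour, itinerary and noise parameters."""

    walk_speed: float = 0.9  # m/s, comfortable indoor pace
    turn_speed_deg_s: float = 120.0
    fixation_median_s: float = 0.30
    fixation_sigma_log: float = 0.35
    fixation_min_s: float = 0.10
    fixation_max_s: float = 1.20
    grouping_probs: tuple = DEFAULT_GROUPING_PROBS
    higher_sizes: tuple = (9, 10, 11, 12, 13)
    env_glance_prob: float = 0.12
    relocation_prob: float = 0.35
    #: mean number of object fixations per trial, per complexity level
    mean_fixations: dict = field(
        default_factory=lambda: {"C_e": 76.56, "C_m": 79.53, "C_h": 121.06}
    )
    #: probability of a correct answer, per complexity level
    accuracy: dict = field(
        default_factory=lambda: {"C_e": 0.961, "C_m": 0.9418, "C_h": 0.912}
    )
    head_pitch_limit_deg: float = 60.0
    head_roll_limit_deg: float = 40.0
    head_yaw_limit_deg: float = 70.0
    vantage_radius_range: tuple = (1.1, 2.1)
    max_trial_s: float = 240.0
    arena: ArenaLayout = field(default_factory=ArenaLayout)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self):
        p = np.asarray(self.grouping_probs, dtype=float)
        if p.shape != (9,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("grouping_probs must be 9 non-negative values summing to 1")

    def mean_group_size(self) -> float:
        sizes = np.array([1, 2, 3, 4, 5, 6, 7, 8, float(np.mean(self.higher_sizes))])
        return float(np.dot(np.asarray(self.grouping_probs), sizes))


@dataclass
class ScheduledFixation:
    t_start: float
    t_end: float
    label: str
    target: tuple


@dataclass
class GroundTruth:
    """Everything the simulator scheduled, for use as a test oracle."""

    fixations: list
    head_path_m: float
    answer: str
    answer_time_s: float
    first_fixation_t: float
    same: bool
    correct: bool
    group_sizes: list
    truncated: bool = False

    def n_fixations(self) -> int:
        return len(self.fixations)

    def labels(self) -> list[str]:
        return [f.label for f in self.fixations]


@dataclass
class TrialSim:
    record: TrialRecord
    head: HeadStream
    gaze: GazeStream
    instances: tuple
    truth: GroundTruth


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

def generate_design(
    n_subjects: int = 47, n_trials: int = 18, seed: int = 0
) -> pd.DataFrame:
    """Factor table for a full experiment.

    Complexity is balanced within subject (n_trials/3 trials per level, in
    shuffled order); start position, orientation difference and sameness
    are uniform random per trial.  Reproducible for a given seed.
    """
    if n_trials % 3 != 0:
        raise InvalidInputError("n_trials must be divisible by 3 to balance complexity")
    rng = np.random.default_rng(seed)
    rows = []
    per_level = n_trials // 3
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        complexities = np.repeat(COMPLEXITIES, per_level)
        rng.shuffle(complexities)
        for t in range(n_trials):
            rows.append(
                {
                    "subject_id": subject_id,
                    "trial_index": t + 1,
                    "complexity": str(complexities[t]),
                    "start_position": str(rng.choice(START_POSITIONS)),
                    "orientation_diff": int(rng.choice(ORIENTATION_LEVELS)),
                    "same": bool(rng.integers(2)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gaze timeline construction
# ---------------------------------------------------------------------------

def _geodesic_point(d0: np.ndarray, d1: np.ndarray, arc_deg: float) -> np.ndarray:
    """Point at ``arc_deg`` along the great circle from d0 toward d1."""
    e = d1 - np.dot(d1, d0) * d0
    n = np.linalg.norm(e)
    if n < 1e-9:
        raise GenerationError("degenerate geodesic (parallel or antipodal directions)")
    e = e / n
    a = math.radians(arc_deg)
    return d0 * math.cos(a) + e * math.sin(a)


def _arc_points(d0: np.ndarray, d1: np.ndarray, arcs: np.ndarray) -> np.ndarray:
    e = d1 - np.dot(d1, d0) * d0
    n = np.linalg.norm(e)
    if n < 1e-9:
        raise GenerationError("degenerate geodesic (parallel or antipodal directions)")
    e = e / n
    a = np.radians(arcs)[:, None]
    return d0[None, :] * np.cos(a) + e[None, :] * np.sin(a)


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return math.degrees(math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0))))


class _GazeTimeline:
    """Appends world gaze directions on the 50 Hz grid, tracking truth."""

    def __init__(self, initial_dir: np.ndarray):
        self.chunks: list[np.ndarray] = [initial_dir[None, :]]
        self.n = 1
        self.cur = initial_dir
        self.fixations: list[ScheduledFixation] = []
        self._hop_tangent: np.ndarray | None = None

    @property
    def t_cur(self) -> float:
        return (self.n - 1) * DT_GAZE

    def _emit(self, dirs: np.ndarray) -> None:
        if dirs.size == 0:
            return
        self.chunks.append(dirs)
        self.n += dirs.shape[0]
        self.cur = dirs[-1]

    def fixate(self, target_point: np.ndarray, eye: np.ndarray, duration_s: float, label: str) -> None:
        d = unit(target_point - eye)
        n = max(6, int(round(duration_s / DT_GAZE)) + 1)
        i0 = self.n
        self._emit(np.tile(d, (n, 1)))
        self.fixations.append(
            ScheduledFixation(
                t_start=i0 * DT_GAZE,
                t_end=(self.n - 1) * DT_GAZE,
                label=label,
                target=tuple(float(x) for x in target_point),
            )
        )
        self._hop_tangent = None

    def saccade_to(self, d1: np.ndarray) -> None:
        """Emit the gap samples of a saccade ending 0.9 deg short of d1."""
        delta = _angle_deg(self.cur, d1)
        if delta < MIN_SACCADE_DEG - 1e-9:
            raise GenerationError(f"saccade amplitude {delta:.2f} deg below minimum")
        lo, hi = STEP_DEG, delta - STEP_DEG
        n_mid = max(0, math.ceil((hi - lo) / MAX_STEP_DEG) - 1)
        arcs = np.linspace(lo, hi, n_mid + 2)
        self._emit(_arc_points(self.cur, d1, arcs))
        self._hop_tangent = None

    def _tangent_toward(self, w: np.ndarray) -> np.ndarray:
        e = w - np.dot(w, self.cur) * self.cur
        n = np.linalg.norm(e)
        return e / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])

    def sweep_to(self, d1: np.ndarray, min_samples: int, rng: np.random.Generator,
                 center_dir: np.ndarray) -> None:
        """Scanning sweep: waypoint hops at ~45 deg/s, then approach d1.

        Emits at least ``min_samples`` samples (covering e.g. a walk), and
        ends 0.9 deg short of d1 so a fixation at d1 may follow.
        """
        emitted0 = self.n
        guard = 0
        while True:
            guard += 1
            if guard > 4000:
                raise GenerationError("sweep construction did not converge")
            delta = _angle_deg(self.cur, d1)
            approach = max(1, round((delta - STEP_DEG) / STEP_DEG)) if delta >= MIN_SACCADE_DEG else 99
            if delta >= MIN_SACCADE_DEG and (self.n - emitted0) + approach >= min_samples:
                break
            self._hop_waypoint(rng, center_dir, d1)
        # final approach: uniform steps from cur to delta - 0.9
        delta = _angle_deg(self.cur, d1)
        hi = delta - STEP_DEG
        n = max(1, int(round(hi / STEP_DEG)))
        arcs = np.linspace(hi / n, hi, n)
        self._emit(_arc_points(self.cur, d1, arcs))
        self._hop_tangent = None

    def _hop_waypoint(self, rng: np.random.Generator, center_dir: np.ndarray,
                      d1: np.ndarray) -> None:
        """One waypoint hop of 8-18 deg with bounded turning angle."""
        for _ in range(40):
            alpha = float(rng.uniform(8.0, 18.0))
            # random tangent direction, constrained to turn <= 60 deg
            phi = rng.uniform(0.0, 2.0 * math.pi)
            helper = np.array([0.0, 0.0, 1.0]) if abs(self.cur[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            u = unit(np.cross(helper, self.cur))
            v = np.cross(self.cur, u)
            tau = math.cos(phi) * u + math.sin(phi) * v
            if self._hop_tangent is not None:
                cosang = float(np.clip(np.dot(tau, self._hop_tangent), -1.0, 1.0))
                if cosang < 0.5:  # turn > 60 deg
                    continue
            w = self.cur * math.cos(math.radians(alpha)) + tau * math.sin(math.radians(alpha))
            if abs(math.degrees(math.asin(np.clip(w[2], -1, 1)))) > 45.0:
                continue
            if _angle_deg(w, center_dir) > 75.0:
                continue
            break
        else:
            # fall back: hop toward the scene center (always admissible)
            tau = self._tangent_toward(center_dir if _angle_deg(self.cur, center_dir) > 5 else d1)
            alpha = 10.0
            w = self.cur * math.cos(math.radians(alpha)) + tau * math.sin(math.radians(alpha))
        n = max(1, int(round(alpha / STEP_DEG)))
        arcs = np.linspace(alpha / n, alpha, n)
        pts = _arc_points(self.cur, w, arcs)
        self._hop_tangent = self._tangent_toward(w)
        self._emit(pts)

    def directions(self) -> np.ndarray:
        return np.concatenate(self.chunks, axis=0)


# ---------------------------------------------------------------------------
# head track
# ---------------------------------------------------------------------------

class _HeadTrack:
    """Piecewise-constant head pose with motion intervals on the 0.1 s grid."""

    def __init__(self, pos0: np.ndarray, quat0: np.ndarray):
        self.t0s: list[float] = []
        self.t1s: list[float] = []
        self.p0s: list[np.ndarray] = []
        self.p1s: list[np.ndarray] = []
        self.q0s: list[np.ndarray] = []
        self.q1s: list[np.ndarray] = []
        self.cur_pos = np.asarray(pos0, float)
        self.cur_quat = np.asarray(quat0, float)
        self.walk_distance = 0.0

    def add_motion(self, t0: float, t1: float, new_pos: np.ndarray | None,
                   new_quat: np.ndarray | None) -> None:
        assert t1 > t0
        assert not self.t1s or t0 >= self.t1s[-1] - 1e-9
        p1 = self.cur_pos if new_pos is None else np.asarray(new_pos, float)
        q1 = self.cur_quat if new_quat is None else np.asarray(new_quat, float)
        self.t0s.append(t0)
        self.t1s.append(t1)
        self.p0s.append(self.cur_pos)
        self.p1s.append(p1)
        self.q0s.append(self.cur_quat)
        self.q1s.append(q1)
        self.walk_distance += float(np.linalg.norm(p1 - self.cur_pos))
        self.cur_pos = p1
        self.cur_quat = q1

    def eval(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, float)
        n = t.shape[0]
        if not self.t0s:
            return np.tile(self.cur_pos, (n, 1)), np.tile(self.cur_quat, (n, 1))
        t0 = np.asarray(self.t0s)
        t1 = np.asarray(self.t1s)
        p0 = np.asarray(self.p0s)
        p1 = np.asarray(self.p1s)
        q0 = np.asarray(self.q0s)
        q1 = np.asarray(self.q1s)
        # index of the last motion interval starting at or before t
        k = np.searchsorted(t0, t, side="right") - 1
        pos = np.empty((n, 3))
        quat = np.empty((n, 4))
        before = k < 0
        if np.any(before):
            pos[before] = p0[0]
            quat[before] = q0[0]
        inside = ~before
        kk = np.clip(k, 0, len(t0) - 1)
        u = np.clip((t - t0[kk]) / (t1[kk] - t0[kk]), 0.0, 1.0)
        pos_in = (1 - u[:, None]) * p0[kk] + u[:, None] * p1[kk]
        quat_in = quat_slerp_many(q0[kk], q1[kk], u)
        pos[inside] = pos_in[inside]
        quat[inside] = quat_in[inside]
        return pos, quat


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _facing_yaw(from_xy: np.ndarray, to_xy: np.ndarray) -> float:
    d = to_xy[:2] - from_xy[:2]
    return math.degrees(math.atan2(d[1], d[0]))


def _sample_vantage(
    rng: np.random.Generator,
    arena: ArenaLayout,
    instances: tuple[ObjectInstance, ObjectInstance],
    params: BehaviorParams,
) -> np.ndarray:
    """Vantage point from which both objects are angularly separable."""
    mid = arena.objects_midpoint()
    c1, c2 = instances[0].center(), instances[1].center()
    r_lo, r_hi = params.vantage_radius_range
    for _ in range(200):
        r = rng.uniform(r_lo, r_hi)
        az = rng.uniform(0.0, 2.0 * math.pi)
        p = np.array([mid[0] + r * math.cos(az), mid[1] + r * math.sin(az), arena.eye_height])
        if not arena.contains(p):
            continue
        d1, d2 = np.linalg.norm(c1 - p), np.linalg.norm(c2 - p)
        if min(d1, d2) < 0.9:
            continue
        sep = _angle_deg(unit(c1 - p), unit(c2 - p))
        ang1 = math.degrees(math.asin(min(1.0, instances[0].bounding_radius / d1)))
        ang2 = math.degrees(math.asin(min(1.0, instances[1].bounding_radius / d2)))
        # objects must not overlap angularly, and each must subtend enough
        # angle that distinct within-object targets stay a saccade apart
        if sep >= ang1 + ang2 + 1.5 and min(ang1, ang2) >= 2.8:
            return p
    raise GenerationError("could not sample an admissible vantage point")


def _object_target(
    inst: ObjectInstance, eye: np.ndarray, prev_dir: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Fixation target on an object, >= 2.4 deg from the previous direction."""
    pts = inst.world_cell_centers()
    for _ in range(40):
        p = pts[rng.integers(len(pts))] + rng.normal(0.0, 0.004, 3)
        if np.linalg.norm(p - inst.center()) > inst.bounding_radius - 1e-6:
            continue
        if _angle_deg(unit(p - eye), prev_dir) >= MIN_SACCADE_DEG:
            return p
    # the cells subtend too little angle from here (e.g. an elongated object
    # seen end-on): synthesize a point inside the bounding sphere on the
    # great circle through the previous direction and the sphere center,
    # far enough past the center to clear the minimum saccade amplitude
    c = inst.center()
    dist = float(np.linalg.norm(c - eye))
    dir_c = unit(c - eye)
    ang_r = math.degrees(math.asin(min(1.0, inst.bounding_radius / dist)))
    base = _angle_deg(prev_dir, dir_c)
    if base < 0.05:
        # previous target is (nearly) dead center: step off sideways far
        # enough that the worst-case achieved angle still clears the minimum
        offset = MIN_SACCADE_DEG + 0.1
        if offset > 0.92 * ang_r:
            raise GenerationError("object subtends too small an angle for a saccade")
        helper = np.array([0.0, 0.0, 1.0]) if abs(dir_c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        tau = unit(np.cross(helper, dir_c))
        new_dir = dir_c * math.cos(math.radians(offset)) + tau * math.sin(math.radians(offset))
    else:
        offset = float(np.clip(MIN_SACCADE_DEG + 0.05 - base, 0.0, 0.92 * ang_r))
        if base + offset < MIN_SACCADE_DEG:
            raise GenerationError("object subtends too small an angle for a saccade")
        if offset <= 1e-9:
            return c
        new_dir = _geodesic_point(prev_dir, dir_c, base + offset)
    return eye + new_dir * dist * math.cos(math.radians(offset))


def _environment_target(
    eye: np.ndarray, toward_dir: np.ndarray, rng: np.random.Generator,
    instances: tuple[ObjectInstance, ObjectInstance], tolerance_deg: float = 1.42,
) -> np.ndarray:
    """A floor point that no object-assignment tolerance can capture."""
    horiz = np.array([toward_dir[0], toward_dir[1], 0.0])
    horiz = unit(horiz) if np.linalg.norm(horiz) > 1e-6 else np.array([1.0, 0.0, 0.0])
    for _ in range(40):
        dist = rng.uniform(0.8, 1.8)
        az_jitter = math.radians(rng.uniform(-25.0, 25.0))
        ca, sa = math.cos(az_jitter), math.sin(az_jitter)
        h = np.array([ca * horiz[0] - sa * horiz[1], sa * horiz[0] + ca * horiz[1], 0.0])
        p = np.array([eye[0] + h[0] * dist, eye[1] + h[1] * dist, 0.0])
        d = unit(p - eye)
        ok = True
        for inst in instances:
            c = inst.center()
            dc = np.linalg.norm(c - eye)
            ang_r = math.degrees(math.asin(min(1.0, inst.bounding_radius / dc)))
            if _angle_deg(d, unit(c - eye)) < ang_r + tolerance_deg + 3.0:
                ok = False
                break
        if ok:
            return p
    raise GenerationError("could not place an environment glance target")


def _draw_group_sizes(
    n_fix_target: float, params: BehaviorParams, rng: np.random.Generator
) -> list[int]:
    """Draw the itinerary's group sizes.

    The number of groups is fixed first and the sizes are then drawn iid
    from the configured categorical distribution; stopping on a cumulative
    fixation count instead would size-bias the final draw and distort the
    pooled run-length distribution.
    """
    goal = max(4.0, rng.normal(n_fix_target, 0.15 * n_fix_target))
    n_groups = max(2, int(round(goal / params.mean_group_size())))
    probs = np.asarray(params.grouping_probs)
    sizes: list[int] = []
    for _ in range(n_groups):
        k = int(rng.choice(9, p=probs))
        sizes.append(k + 1 if k < 8 else int(rng.choice(params.higher_sizes)))
    return sizes


def simulate_trial(
    trial: dict | pd.Series, params: BehaviorParams | None = None,
    seed: int | np.random.Generator = 0,
) -> TrialSim:
    """Simulate one trial; see the module docstring for the model."""
    params = params or BehaviorParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arena = params.arena
    t = dict(trial)

    instances = make_stimulus_pair(
        t["complexity"], bool(t["same"]), float(t["orientation_diff"]), rng,
        positions=[np.asarray(p, float) for p in arena.post_positions],
    )
    centers = (instances[0].center(), instances[1].center())
    mid = arena.objects_midpoint()

    start = arena.start_position(t["start_position"])
    yaw_face = _facing_yaw(start, mid)
    yaw_away = yaw_face + 172.0  # just off 180 so the turn direction is defined
    q_away = quat_from_yaw(yaw_away)
    head = _HeadTrack(start, q_away)

    init_dir = quat_rotate(q_away, np.array([1.0, 0.0, 0.0]))
    timeline = _GazeTimeline(init_dir)

    # --- turn in place, then walk to the first vantage point -----------------
    vantage = _sample_vantage(rng, arena, instances, params)
    turn_needed = 172.0
    turn_dur = MOTION_GRID * math.ceil(turn_needed / params.turn_speed_deg_s / MOTION_GRID)
    t_turn0 = MOTION_GRID
    head.add_motion(t_turn0, t_turn0 + turn_dur, None, quat_from_yaw(yaw_face))
    dist = float(np.linalg.norm(vantage - start))
    walk_dur = MOTION_GRID * max(1, math.ceil(dist / params.walk_speed / MOTION_GRID))
    t_w0 = t_turn0 + turn_dur
    head.add_motion(t_w0, t_w0 + walk_dur, vantage, quat_from_yaw(_facing_yaw(vantage, mid)))
    eye = vantage

    group_sizes = _draw_group_sizes(params.mean_fixations[t["complexity"]], params, rng)
    obj = int(rng.integers(2))
    first_target = _object_target(instances[obj], eye, timeline.cur, rng)
    center_dir = unit(mid - eye)
    need = math.ceil((t_w0 + walk_dur + 0.06 - timeline.t_cur) / DT_GAZE)
    timeline.sweep_to(unit(first_target - eye), need, rng, center_dir)

    # --- inspection itinerary ------------------------------------------------
    truncated = False
    scheduled_groups: list[int] = []
    pending_target = first_target
    for g, size in enumerate(group_sizes):
        if timeline.t_cur > params.max_trial_s:
            truncated = True
            log.warning("trial itinerary truncated at %.1f s", timeline.t_cur)
            break
        if g > 0:
            obj = 1 - obj
            # optional relocation to a new vantage point
            if rng.uniform() < params.relocation_prob:
                try:
                    new_v = _sample_vantage(rng, arena, instances, params)
                except GenerationError:
                    new_v = eye
                if np.linalg.norm(new_v - eye) > 0.3:
                    t_w0 = MOTION_GRID * math.ceil((timeline.t_cur + 0.12) / MOTION_GRID)
                    dist = float(np.linalg.norm(new_v - eye))
                    walk_dur = MOTION_GRID * max(1, math.ceil(dist / params.walk_speed / MOTION_GRID))
                    head.add_motion(
                        t_w0, t_w0 + walk_dur, new_v, quat_from_yaw(_facing_yaw(new_v, mid))
                    )
                    eye = new_v
                    target = _object_target(instances[obj], eye, timeline.cur, rng)
                    need = math.ceil((t_w0 + walk_dur + 0.06 - timeline.t_cur) / DT_GAZE)
                    timeline.sweep_to(unit(target - eye), need, rng, unit(mid - eye))
                    pending_target = target
                else:
                    pending_target = None
            else:
                pending_target = None
            # optional environment glance between groups
            if rng.uniform() < params.env_glance_prob:
                env_p = _environment_target(eye, unit(centers[obj] - eye), rng, instances)
                timeline.saccade_to(unit(env_p - eye))
                timeline.fixate(env_p, eye, _fix_duration(params, rng), "environment")
                pending_target = None
        for j in range(size):
            if pending_target is not None and j == 0:
                target = pending_target
                pending_target = None
            else:
                target = _object_target(instances[obj], eye, timeline.cur, rng)
                timeline.saccade_to(unit(target - eye))
            if timeline.cur is not None and _angle_deg(timeline.cur, unit(target - eye)) > STEP_DEG + 1e-6:
                # a sweep left us short of the target only by the design step;
                # anything larger means a saccade is still pending
                timeline.saccade_to(unit(target - eye))
            timeline.fixate(target, eye, _fix_duration(params, rng), f"object{obj + 1}")
        scheduled_groups.append(size)

    # --- outro: look away toward the experimenter, then stop -----------------
    _emit_outro(timeline, rng)

    answer_time = timeline.t_cur
    truth_correct = bool(rng.uniform() < params.accuracy[t["complexity"]])
    truth_same = bool(t["same"])
    right = "same" if truth_same else "different"
    wrong = "different" if truth_same else "same"
    answer = right if truth_correct else wrong

    record = TrialRecord(
        subject_id=str(t["subject_id"]),
        trial_index=int(t["trial_index"]),
        complexity=str(t["complexity"]),
        start_position=str(t["start_position"]),
        orientation_diff=int(t["orientation_diff"]),
        same=truth_same,
        answer=answer,
        answer_time=answer_time,
    )

    head_stream, gaze_stream = _materialize_streams(timeline, head, params, rng)

    truth = GroundTruth(
        fixations=timeline.fixations,
        head_path_m=head.walk_distance,
        answer=answer,
        answer_time_s=answer_time,
        first_fixation_t=timeline.fixations[0].t_start if timeline.fixations else float("nan"),
        same=truth_same,
        correct=truth_correct,
        group_sizes=scheduled_groups,
        truncated=truncated,
    )
    return TrialSim(record=record, head=head_stream, gaze=gaze_stream,
                    instances=instances, truth=truth)


def _fix_duration(params: BehaviorParams, rng: np.random.Generator) -> float:
    d = rng.lognormal(math.log(params.fixation_median_s), params.fixation_sigma_log)
    return float(np.clip(d, params.fixation_min_s, params.fixation_max_s))


def _emit_outro(timeline: _GazeTimeline, rng: np.random.Generator) -> None:
    """Short post-answer gaze shift so the trace never ends inside a fixation."""
    helper = np.array([0.0, 0.0, 1.0]) if abs(timeline.cur[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = unit(np.cross(helper, timeline.cur))
    w = timeline.cur * math.cos(math.radians(20.0)) + u * math.sin(math.radians(20.0))
    timeline.saccade_to(w)


def _materialize_streams(
    timeline: _GazeTimeline, head: _HeadTrack, params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[HeadStream, GazeStream]:
    dirs_world = timeline.directions()
    n_gaze = dirs_world.shape[0]
    t_gaze = np.arange(n_gaze) * DT_GAZE
    t_end = t_gaze[-1]
    n_head = int(math.ceil(t_end * 120.0 - 1e-9)) + 1
    if (n_head - 1) / 120.0 < t_end - 1e-12:
        n_head += 1
    t_head = np.arange(n_head) / 120.0
    head_pos, head_quat = head.eval(t_head)
    gaze_pos, gaze_quat = head.eval(t_gaze)
    dir_head = quat_rotate_inverse(gaze_quat, dirs_world)
    dir_head /= np.linalg.norm(dir_head, axis=1, keepdims=True)

    if params.noise.enabled:
        sigma_ar = params.noise.gaze_ar_sigma_deg()
        rho = math.exp(-DT_GAZE / params.noise.gaze_ar_tau_s)
        e = np.empty((n_gaze, 2))
        for c in range(2):
            innov = rng.normal(0.0, 1.0, n_gaze) * math.sqrt(1.0 - rho**2)
            x0 = rng.normal(0.0, 1.0)
            series = lfilter([1.0], [1.0, -rho], innov, zi=[rho * x0])[0]
            e[:, c] = sigma_ar * series
        e += rng.normal(0.0, params.noise.gaze_jitter_rms_deg / math.sqrt(2.0), (n_gaze, 2))
        dir_head = _perturb_dirs(dir_head, e)
        head_pos = head_pos + rng.normal(
            0.0, params.noise.head_rmse_m / math.sqrt(3.0), head_pos.shape
        )

    head_stream = HeadStream(t=t_head, position=head_pos, quat=head_quat)
    gaze_stream = GazeStream(
        t=t_gaze, direction=dir_head, valid=np.ones(n_gaze, dtype=bool)
    )
    return head_stream, gaze_stream


def _perturb_dirs(dirs: np.ndarray, err_deg: np.ndarray) -> np.ndarray:
    """Rotate each direction by tangential offsets (degrees, two components)."""
    helper = np.where(
        np.abs(dirs[:, 2:3]) < 0.9,
        np.tile(np.array([0.0, 0.0, 1.0]), (dirs.shape[0], 1)),
        np.tile(np.array([1.0, 0.0, 0.0]), (dirs.shape[0], 1)),
    )
    u = np.cross(helper, dirs)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(dirs, u)
    w = np.radians(err_deg[:, 0:1]) * u + np.radians(err_deg[:, 1:2]) * v
    eps = np.linalg.norm(w, axis=1, keepdims=True)
    small = eps[:, 0] < 1e-12
    axis = np.where(small[:, None], u, w / np.where(eps == 0, 1.0, eps))
    out = dirs * np.cos(eps) + axis * np.sin(eps)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# experiment-level simulation
# ---------------------------------------------------------------------------

def trial_dirname(subject_id: str, trial_index: int) -> str:
    return f"{subject_id}_T{trial_index:02d}"


def _truth_to_dict(truth: GroundTruth) -> dict:
    d = asdict(truth)
    d["fixations"] = [asdict(f) for f in truth.fixations]
    return d


def truth_from_dict(d: dict) -> GroundTruth:
    fixes = [ScheduledFixation(**f) for f in d["fixations"]]
    kwargs = dict(d)
    kwargs["fixations"] = fixes
    kwargs["fixations"] = [
        ScheduledFixation(f["t_start"], f["t_end"], f["label"], tuple(f["target"]))
        for f in d["fixations"]
    ]
    return GroundTruth(**kwargs)


def simulate_experiment(
    design: pd.DataFrame, params: BehaviorParams | None = None,
    seed: int = 0, outdir: str | Path = "simulated",
) -> Path:
    """Simulate every trial of a design and write a file tree.

    One sub-directory per trial with ``head.csv``, ``gaze.csv``,
    ``objects.json``, ``object_poses.csv``, ``trial.json`` and
    ``truth.json``, plus a top-level ``manifest.json``.  Byte-identical
    across runs for a fixed seed.
    """
    params = params or BehaviorParams()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "n_trials": int(len(design)), "trials": []}
    for i, row in enumerate(design.to_dict("records")):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,))))
        sim = simulate_trial(row, params, rng)
        name = trial_dirname(row["subject_id"], int(row["trial_index"]))
        tdir = out / name
        tdir.mkdir(exist_ok=True)
        write_head_csv(tdir / "head.csv", sim.head)
        write_gaze_csv(tdir / "gaze.csv", sim.gaze)
        with open(tdir / "objects.json", "w") as fh:
            json.dump([instance_to_dict(inst) for inst in sim.instances], fh, indent=1)
        _write_object_poses(tdir / "object_poses.csv", sim.instances)
        rec = sim.record
        write_trial_json(
            tdir / "trial.json",
            {
                "subject_id": rec.subject_id,
                "trial_index": rec.trial_index,
                "complexity": rec.complexity,
                "start_position": rec.start_position,
                "orientation_diff_deg": rec.orientation_diff,
                "same": rec.same,
                "answer": rec.answer,
                "answer_time_s": rec.answer_time,
            },
        )
        with open(tdir / "truth.json", "w") as fh:
            json.dump(_truth_to_dict(sim.truth), fh, indent=1)
        manifest["trials"].append({"dir": name, "subject_id": rec.subject_id,
                                   "trial_index": rec.trial_index})
        log.info("simulated %s: %d fixations, %.1f s", name,
                 len(sim.truth.fixations), sim.truth.answer_time_s)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _write_object_poses(path, instances) -> None:
    rows = []
    for k, inst in enumerate(instances):
        rows.append(
            [inst.pose.t, f"object{k + 1}", *inst.pose.position, *inst.pose.orientation]
        )
    pd.DataFrame(
        rows, columns=["t_s", "object_id", "px_m", "py_m", "pz_m", "qw", "qx", "qy", "qz"]
    ).to_csv(path, index=False)
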