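"""Velocity-threshold (I-VT) fixation detection on synchronized gaze.

A fixation is a maximal run of gaze samples whose angular velocity stays
below a threshold (default 30 deg/s).  Velocity is computed on
*world-frame* gaze directions by default, so that smooth head translation
while fixating a static object (VOR-like behaviour) still registers as a
fixation; head-frame mode is available via ``FixationDetectorConfig.frame``.

Event treatment follows standard I-VT practice: adjacent sub-threshold
runs separated by a short gap with nearly identical directions are merged
(repairing single-sample noise blips), then runs shorter than a minimum
duration are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import Ray, angle_between_deg, angular_velocity_series, unit
from .streams import SyncedStream

__all__ = ["FixationDetectorConfig", "Fixation", "detect_fixations",
           "write_fixations_csv", "read_fixations_csv"]

log = logging.getLogger(__name__)

LABELS = ("object1", "object2", "environment", "unassigned")


@dataclass
class FixationDetectorConfig:
    """I-VT parameters.

    velocity_threshold : deg/s below which a sample counts as fixational.
    min_duration : shortest event kept, seconds.
    max_gap : longest gap across which two runs may be merged, seconds.
    merge_max_angle : largest mean-direction difference (degrees) allowed
        for a merge; keeps pre-/post-saccade fixations apart.
    frame : "world" or "head" — which directions feed the velocity estimate.
    """

    velocity_threshold: float = 30.0
    min_duration: float = 0.060
    max_gap: float = 0.075
    merge_max_angle: float = 0.5
    frame: str = "world"

    def __post_init__(self):
        if self.velocity_threshold <= 0:
            raise InvalidInputError("velocity_threshold must be positive")
        if self.min_duration < 0 or self.max_gap < 0:
            raise InvalidInputError("durations must be >= 0")
        if self.frame not in ("world", "head"):
            raise InvalidInputError("frame must be 'world' or 'head'")


@dataclass
class Fixation:
    """One detected fixation event."""

    t_start: float
    t_end: float
    mean_ray: Ray
    n_samples: int
    label: str = "unassigned"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise InvalidInputError("fixation must have t_end > t_start")
        if self.n_samples < 2:
            raise InvalidInputError("fixation needs at least 2 samples")
        if self.label not in LABELS:
            raise InvalidInputError(f"unknown fixation label {self.label!r}")


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop] (inclusive) index runs where mask is True."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def _mean_dir(dirs: np.ndarray) -> np.ndarray:
    return unit(dirs.mean(axis=0), "mean gaze direction")


def detect_fixations(synced: SyncedStream, cfg: FixationDetectorConfig | None = None) -> list[Fixation]:
    """Classify a synchronized stream into fixation events.

    Returns fixations in time order, non-overlapping, each labelled
    ``unassigned``.
    """
    cfg = cfg or FixationDetectorConfig()
    if len(synced) < 2:
        raise InvalidInputError("need at least 2 synchronized samples")
    dirs = synced.gaze_dir_world if cfg.frame == "world" else synced.gaze_dir_head
    t = synced.t
    vel = angular_velocity_series(dirs, t)
    runs = _runs_of(vel < cfg.velocity_threshold)
    # single-sample runs can never become fixations (n_samples >= 2) and a
    # lone sub-threshold sample inside a saccade must not block merging
    runs = [r for r in runs if r[1] > r[0]]

    # merge adjacent runs across short, angularly consistent gaps; the gap
    # is the unclassified time strictly between the two runs
    dt_nominal = float(np.median(np.diff(t)))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged:
            p0, p1 = merged[-1]
            gap = t[run[0]] - t[p1] - dt_nominal
            if gap <= cfg.max_gap:
                drift = angle_between_deg(_mean_dir(dirs[p0 : p1 + 1]), _mean_dir(dirs[run[0] : run[1] + 1]))
                if drift <= cfg.merge_max_angle:
                    merged[-1] = (p0, run[1])
                    continue
        merged.append(run)

    fixations: list[Fixation] = []
    for i0, i1 in merged:
        if i1 - i0 + 1 < 2:
            continue
        duration = t[i1] - t[i0]
        if duration < cfg.min_duration:
            continue
        seg = slice(i0, i1 + 1)
        fixations.append(
            Fixation(
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                mean_ray=Ray(
                    origin=synced.head_position[seg].mean(axis=0),
                    direction=_mean_dir(synced.gaze_dir_world[seg]),
                ),
                n_samples=int(i1 - i0 + 1),
            )
        )
    log.debug("detect_fixations: %d raw runs -> %d fixations", len(runs), len(fixations))
    return fixations


FIXATION_COLUMNS = [
    "t_start_s", "t_end_s", "duration_s",
    "ox", "oy", "oz", "dx", "dy", "dz", "n_samples", "label",
]


def write_fixations_csv(path, fixations: list[Fixation]) -> None:
    rows = [
        [f.t_start, f.t_end, f.duration, *f.mean_ray.origin, *f.mean_ray.direction,
         f.n_samples, f.label]
        for f in fixations
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def read_fixations_csv(path) -> list[Fixation]:
    df = pd.read_csv(path)
    return [
        Fixation(
            t_start=row.t_start_s,
            t_end=row.t_end_s,
            mean_ray=Ray(np.array([row.ox, row.oy, row.oz]), np.array([row.dx, row.dy, row.dz])),
            n_samples=int(row.n_samples),
            label=row.label,
        )
        for row in df.itertuples()
    ]
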