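"""Stream file formats and head/gaze synchronization.

Two raw streams feed the pipeline:

* **head** — 6-DOF head pose at a nominal 120 Hz
  (CSV columns ``t_s, px_m, py_m, pz_m, qw, qx, qy, qz``);
* **gaze** — unit gaze direction *in the head frame* at a nominal 50 Hz
  (CSV columns ``t_s, gx, gy, gz, valid``).

Timestamps are trial-relative float seconds with microsecond resolution,
``t = 0`` at the first head sample.  ``synchronize`` interpolates the
higher-rate head stream to each valid gaze timestamp (gaze is the
lower-rate, event-defining stream) and rotates the head-frame gaze
direction into the world frame, producing one world gaze ray per kept
gaze sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, SynchronizationError
from .geometry import quat_rotate, quat_slerp_many

__all__ = [
    "HeadStream",
    "GazeStream",
    "SyncedStream",
    "read_head_csv",
    "write_head_csv",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_streams",
    "read_trial_json",
    "write_trial_json",
    "synchronize",
]

log = logging.getLogger(__name__)

HEAD_COLUMNS = ["t_s", "px_m", "py_m", "pz_m", "qw", "qx", "qy", "qz"]
GAZE_COLUMNS = ["t_s", "gx", "gy", "gz", "valid"]

#: head gaps longer than this (three nominal 120 Hz periods) are not
#: interpolated across; gaze samples falling inside are dropped.
MAX_HEAD_GAP_S = 0.025


def _check_monotonic(t: np.ndarray, what: str, path) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise FormatError(
            f"{what} timestamps not strictly increasing in {path} at data row {row} (t={t[row]!r})"
        )


@dataclass
class HeadStream:
    """Timestamped head poses: t (N,), position (N, 3), quat (N, 4) wxyz."""

    t: np.ndarray
    position: np.ndarray
    quat: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        n = self.t.shape[0]
        if self.position.shape != (n, 3) or self.quat.shape != (n, 4):
            raise InvalidInputError("inconsistent head stream array shapes")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("head timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class GazeStream:
    """Timestamped head-frame gaze directions with a validity flag."""

    t: np.ndarray
    direction: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.shape[0]
        if self.direction.shape != (n, 3) or self.valid.shape != (n,):
            raise InvalidInputError("inconsistent gaze stream array shapes")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class SyncedStream:
    """Merged record at gaze timestamps: head pose + world gaze ray."""

    t: np.ndarray
    head_position: np.ndarray
    head_quat: np.ndarray
    gaze_dir_head: np.ndarray
    gaze_dir_world: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def ray_origins(self) -> np.ndarray:
        return self.head_position


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s) {missing}")
    return df


def read_head_csv(path) -> HeadStream:
    df = _read_csv(path, HEAD_COLUMNS)
    t = df["t_s"].to_numpy(float)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"non-finite timestamp in {path}")
    _check_monotonic(t, "head", path)
    pos = df[["px_m", "py_m", "pz_m"]].to_numpy(float)
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(quat)):
        raise FormatError(f"non-finite head pose values in {path}")
    norms = np.linalg.norm(quat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        row = int(np.argmax(np.abs(norms - 1.0))) + 1
        raise FormatError(f"non-unit quaternion in {path} at data row {row}")
    return HeadStream(t=t, position=pos, quat=quat)


def write_head_csv(path, head: HeadStream) -> None:
    df = pd.DataFrame(
        np.column_stack([head.t, head.position, head.quat]), columns=HEAD_COLUMNS
    )
    df.to_csv(path, index=False)


def read_gaze_csv(path) -> GazeStream:
    df = _read_csv(path, GAZE_COLUMNS)
    t = df["t_s"].to_numpy(float)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"non-finite timestamp in {path}")
    _check_monotonic(t, "gaze", path)
    dirs = df[["gx", "gy", "gz"]].to_numpy(float)
    valid = df["valid"].to_numpy(float) != 0
    # rows with a bad direction are flagged invalid, never dropped
    finite = np.all(np.isfinite(dirs), axis=1)
    norms = np.where(finite, np.linalg.norm(np.nan_to_num(dirs), axis=1), 0.0)
    usable = finite & (np.abs(norms - 1.0) < 1e-6)
    n_flagged = int(np.sum(valid & ~usable))
    if n_flagged:
        log.warning("%s: flagged %d gaze rows with invalid directions", path, n_flagged)
    valid = valid & usable
    dirs = np.where(np.isfinite(dirs), dirs, 0.0)
    return GazeStream(t=t, direction=dirs, valid=valid)


def write_gaze_csv(path, gaze: GazeStream) -> None:
    df = pd.DataFrame(
        np.column_stack([gaze.t, gaze.direction, gaze.valid.astype(int)]),
        columns=GAZE_COLUMNS,
    )
    df["valid"] = df["valid"].astype(int)
    df.to_csv(path, index=False)


def read_streams(head_path, gaze_path) -> tuple[HeadStream, GazeStream]:
    """Parse and validate a head/gaze stream pair."""
    return read_head_csv(head_path), read_gaze_csv(gaze_path)


_TRIAL_KEYS = [
    "subject_id",
    "trial_index",
    "complexity",
    "start_position",
    "orientation_diff_deg",
    "same",
    "answer",
    "answer_time_s",
]


def read_trial_json(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    missing = [k for k in _TRIAL_KEYS if k not in d]
    if missing:
        raise FormatError(f"{path} is missing trial field(s) {missing}")
    return d


def write_trial_json(path, trial: dict) -> None:
    with open(path, "w") as fh:
        json.dump({k: trial[k] for k in _TRIAL_KEYS}, fh, indent=1)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def synchronize(
    head: HeadStream, gaze: GazeStream, max_head_gap: float = MAX_HEAD_GAP_S
) -> SyncedStream:
    """Interpolate head poses to gaze timestamps and build world gaze rays.

    For each *valid* gaze sample inside the head stream's time span the
    head pose is slerp-interpolated to the gaze timestamp and the
    head-frame gaze direction is rotated into the world frame; the ray
    origin is the interpolated head position.  Gaze samples outside the
    span, or bridging a head gap longer than ``max_head_gap``, are dropped
    (counts are logged).
    """
    if len(head) < 2:
        raise SynchronizationError("head stream too short to interpolate")
    t0, t1 = head.t[0], head.t[-1]
    in_span = (gaze.t >= t0) & (gaze.t <= t1)
    keep = in_span & gaze.valid
    n_out = int(np.sum(gaze.valid & ~in_span))
    tg = gaze.t[keep]
    if tg.size == 0:
        raise SynchronizationError("no valid gaze samples within the head stream span")
    idx = np.searchsorted(head.t, tg, side="right") - 1
    idx = np.clip(idx, 0, len(head) - 2)
    gap = head.t[idx + 1] - head.t[idx]
    bridgeable = gap <= max_head_gap
    exact = tg == head.t[idx]  # exact hits never need interpolation
    ok = bridgeable | exact
    n_gap = int(np.sum(~ok))
    if n_gap:
        keep_idx = np.nonzero(keep)[0][~ok]
        keep[keep_idx] = False
        tg = tg[ok]
        idx = idx[ok]
        gap = gap[ok]
    if n_out or n_gap:
        log.info(
            "synchronize: dropped %d gaze samples outside head span, %d in head gaps",
            n_out,
            n_gap,
        )
    if tg.size == 0:
        raise SynchronizationError("all gaze samples fall in head-stream gaps")
    u = (tg - head.t[idx]) / gap
    pos = (1.0 - u[:, None]) * head.position[idx] + u[:, None] * head.position[idx + 1]
    quat = quat_slerp_many(head.quat[idx], head.quat[idx + 1], u)
    dir_head = gaze.direction[keep]
    dir_world = quat_rotate(quat, dir_head)
    dir_world /= np.linalg.norm(dir_world, axis=1, keepdims=True)
    return SyncedStream(
        t=tg,
        head_position=pos,
        head_quat=quat,
        gaze_dir_head=dir_head,
        gaze_dir_world=dir_world,
    )
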