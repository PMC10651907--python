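"""Per-trial dependent measures.

For each trial of the 2AFC same-different task the pipeline reports:

* correctness of the answer;
* response time — seconds from the first fixation of the trial to the
  moment the answer was given;
* fixation counts per label (object 1 / object 2 / environment);
* head-movement extent — anchored path length of the head trajectory;
* fixation ratio — shares of object fixations on the primary
  (more-fixated) and secondary object;
* grouping profile — run lengths of consecutive fixations on one object
  before focus moves to the other, binned single, couple, ..., octuple
  and "higher" (> 8);
* normalized response time — mean response time per block element of the
  stimulus.

Environment fixations are removed before run-length encoding and by
default do *not* split a run: an orientation glance at the floor in the
middle of inspecting an object does not end the inspection episode.  A
split mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fixations import Fixation
from .geometry import path_length
from .streams import HeadStream

__all__ = [
    "TrialRecord",
    "GroupingProfile",
    "TrialMetrics",
    "response_time",
    "grouping_profile",
    "fixation_ratio",
    "normalized_response_time",
    "summarize_trial",
    "metrics_table",
]

log = logging.getLogger(__name__)

COMPLEXITIES = ("C_e", "C_m", "C_h")
START_POSITIONS = ("P_l", "P_s", "P_c")
ORIENTATION_LEVELS = (0, 90, 180)

GROUP_BIN_NAMES = (
    "single", "couple", "triple", "quadruple",
    "quintuple", "sextuple", "septuple", "octuple", "higher",
)


@dataclass
class TrialRecord:
    """Trial factors plus the subject's answer."""

    subject_id: str
    trial_index: int
    complexity: str
    start_position: str
    orientation_diff: int
    same: bool
    answer: str
    answer_time: float

    def __post_init__(self):
        if self.complexity not in COMPLEXITIES:
            raise InvalidInputError(f"unknown complexity {self.complexity!r}")
        if self.start_position not in START_POSITIONS:
            raise InvalidInputError(f"unknown start position {self.start_position!r}")
        if int(self.orientation_diff) not in ORIENTATION_LEVELS:
            raise InvalidInputError(f"orientation difference must be one of {ORIENTATION_LEVELS}")
        if self.answer not in ("same", "different"):
            raise InvalidInputError("answer must be 'same' or 'different'")
        if self.answer_time <= 0:
            raise InvalidInputError("answer_time must be positive")

    @property
    def correct(self) -> bool:
        return self.answer == ("same" if self.same else "different")


@dataclass
class GroupingProfile:
    """Run-length histogram of object-fixation groupings.

    counts[k] is the number of runs of length k+1 for k = 0..7; counts[8]
    collects runs longer than 8.  ``run_lengths`` keeps the exact lengths
    so that totals can be audited without bin midpoints.
    """

    counts: np.ndarray
    run_lengths: tuple

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_fixations(self) -> int:
        return int(sum(self.run_lengths))

    @property
    def shares(self) -> np.ndarray:
        """Percent share per bin; zeros when there are no runs."""
        tot = self.total_runs
        if tot == 0:
            return np.zeros(9)
        return self.counts / tot * 100.0

    def as_dict(self) -> dict:
        return {name: int(c) for name, c in zip(GROUP_BIN_NAMES, self.counts)}


@dataclass
class TrialMetrics:
    """All derived measures for one trial."""

    correct: bool
    response_time: float | None
    n_fix_obj1: int
    n_fix_obj2: int
    n_fix_env: int
    head_path: float
    primary_share: float | None
    secondary_share: float | None
    primary_id: str | None
    grouping: GroupingProfile
    flags: list = field(default_factory=list)


def response_time(first_fix_start: float, answer_time: float) -> float:
    """Seconds elapsed from the first fixation to the answer."""
    if answer_time <= first_fix_start:
        raise InvalidInputError("answer precedes the first fixation")
    return float(answer_time - first_fix_start)


def _object_runs(labels, split_on_environment: bool) -> list[int]:
    runs: list[int] = []
    prev = None
    for lab in labels:
        if lab == "environment":
            if split_on_environment:
                prev = None
            continue
        if lab not in ("object1", "object2"):
            continue
        if lab == prev:
            runs[-1] += 1
        else:
            runs.append(1)
            prev = lab
    return runs


def grouping_profile(labels, split_on_environment: bool = False) -> GroupingProfile:
    """Tabulate object-fixation run lengths into bins 1..8 and > 8.

    Environment labels are removed first; with the default
    ``split_on_environment=False`` they do not interrupt a run.
    """
    runs = _object_runs(list(labels), split_on_environment)
    counts = np.zeros(9, dtype=int)
    for r in runs:
        counts[min(r, 9) - 1] += 1
    return GroupingProfile(counts=counts, run_lengths=tuple(runs))


def fixation_ratio(labels) -> tuple[float, float, str]:
    """Primary/secondary object-fixation shares in percent.

    The primary object is the one with more object fixations; an exact tie
    resolves to the object fixated first.  Shares sum to 100.
    """
    obj = [lab for lab in labels if lab in ("object1", "object2")]
    if not obj:
        raise InvalidInputError("fixation ratio undefined without object fixations")
    n1 = obj.count("object1")
    n2 = len(obj) - n1
    if n1 > n2:
        primary = "object1"
    elif n2 > n1:
        primary = "object2"
    else:
        primary = obj[0]
    n_primary = n1 if primary == "object1" else n2
    share = n_primary / len(obj) * 100.0
    return float(share), float(100.0 - share), primary


def normalized_response_time(mean_rt: float, n_blocks: int) -> float:
    """Mean response time per stimulus element, rounded to 2 decimals."""
    if n_blocks < 1:
        raise InvalidInputError("block count must be >= 1")
    return round(float(mean_rt) / n_blocks, 2)


def summarize_trial(
    record: TrialRecord,
    fixations: list[Fixation],
    head: HeadStream,
    *,
    min_step: float = 0.002,
    split_on_environment: bool = False,
) -> TrialMetrics:
    """Populate every per-trial measure from labelled fixations and the
    head stream.  Undefined sub-metrics are flagged, never silently
    dropped."""
    flags: list[str] = []
    labels = [f.label for f in fixations]
    n1 = labels.count("object1")
    n2 = labels.count("object2")
    nenv = labels.count("environment")
    if fixations:
        try:
            rt = response_time(fixations[0].t_start, record.answer_time)
        except InvalidInputError:
            rt = None
            flags.append("answer_before_first_fixation")
    else:
        rt = None
        flags.append("no_fixations")
    try:
        p_share, s_share, p_id = fixation_ratio(labels)
    except InvalidInputError:
        p_share = s_share = p_id = None
        flags.append("no_object_fixations")
    head_path = path_length(head.position, min_step=min_step)
    return TrialMetrics(
        correct=record.correct,
        response_time=rt,
        n_fix_obj1=n1,
        n_fix_obj2=n2,
        n_fix_env=nenv,
        head_path=head_path,
        primary_share=p_share,
        secondary_share=s_share,
        primary_id=p_id,
        grouping=grouping_profile(labels, split_on_environment),
        flags=flags,
    )


def metrics_row(record: TrialRecord, m: TrialMetrics) -> dict:
    row = {
        "subject_id": record.subject_id,
        "trial_index": record.trial_index,
        "complexity": record.complexity,
        "start_position": record.start_position,
        "orientation_diff": record.orientation_diff,
        "same": record.same,
        "answer": record.answer,
        "answer_time_s": record.answer_time,
        "correct": m.correct,
        "response_time_s": m.response_time,
        "n_fix_obj1": m.n_fix_obj1,
        "n_fix_obj2": m.n_fix_obj2,
        "n_fix_obj": m.n_fix_obj1 + m.n_fix_obj2,
        "n_fix_env": m.n_fix_env,
        "head_path_m": m.head_path,
        "primary_share": m.primary_share,
        "secondary_share": m.secondary_share,
        "primary_id": m.primary_id,
        "flags": ";".join(m.flags),
    }
    for name, share in zip(GROUP_BIN_NAMES, m.grouping.shares):
        row[f"share_{name}"] = share
    for name, count in zip(GROUP_BIN_NAMES, m.grouping.counts):
        row[f"count_{name}"] = int(count)
    return row


def metrics_table(records: list[TrialRecord], metrics: list[TrialMetrics]) -> pd.DataFrame:
    """One row per trial, columns for every factor and measure."""
    return pd.DataFrame([metrics_row(r, m) for r, m in zip(records, metrics)])
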