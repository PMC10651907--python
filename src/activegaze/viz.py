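"""Minimal top-down (floor-plane) visualization of a trial.

A 2D convenience plot: head trajectory, fixation rays colored by label,
and the two stimulus footprints.  Anything fancier (3D frusta, video
overlays) is out of scope.
"""

from __future__ import annotations

import numpy as np

from .fixations import Fixation
from .stimuli import ObjectInstance
from .streams import HeadStream

_LABEL_COLORS = {
    "object1": "tab:red",
    "object2": "tab:blue",
    "environment": "0.6",
    "unassigned": "0.3",
}


def plot_trial_topdown(
    head: HeadStream,
    fixations: list[Fixation],
    instances: tuple[ObjectInstance, ObjectInstance],
    ax=None,
    ray_length: float = 0.6,
):
    """Draw the trial on a matplotlib axis (created if not given)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    ax.plot(head.position[:, 0], head.position[:, 1], color="0.75", lw=0.8,
            label="head path")
    for fix in fixations:
        o = fix.mean_ray.origin
        d = fix.mean_ray.direction
        ax.plot(
            [o[0], o[0] + ray_length * d[0]],
            [o[1], o[1] + ray_length * d[1]],
            color=_LABEL_COLORS.get(fix.label, "k"),
            lw=0.6,
            alpha=0.6,
        )
    for k, inst in enumerate(instances):
        c = inst.center()
        circle = plt.Circle(
            (c[0], c[1]), inst.bounding_radius,
            color=_LABEL_COLORS[f"object{k + 1}"], fill=False, lw=1.5,
        )
        ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax
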