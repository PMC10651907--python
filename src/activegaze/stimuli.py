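"""Polycube stimulus model: complexity, congruence, poses and generation.

The stimuli of the task are block-built objects: connected sets of unit
cubes glued face-to-face on an integer lattice, mounted on acrylic posts.
Two objects are "the same" iff they are geometrically congruent under a
*proper* rotation: the 24 orientation-preserving symmetries of the cubic
lattice.  Mirror images count as different — the stimuli are rigid
physical objects and a chiral pair is visually distinguishable.

Complexity is keyed to block count: C_e (easy, n = 7), C_m (medium,
n = 10), C_h (hard, n = 18).  The default lattice cell size of 3 cm keeps
an 18-block object inside the ~12 x 14 x 18 cm physical envelope of the
original stimuli.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, InvalidInputError
from .geometry import (
    Pose6DOF,
    angular_difference,
    quat_from_yaw,
    quat_multiply,
    quat_rotate,
)

__all__ = [
    "COMPLEXITY_LEVELS",
    "COMPLEXITY_BLOCKS",
    "BLOCKS_TO_COMPLEXITY",
    "PolycubeObject",
    "ObjectInstance",
    "canonical_form",
    "are_congruent",
    "orientation_difference",
    "generate_random_polycube",
    "make_stimulus_pair",
    "proper_lattice_rotations",
]

COMPLEXITY_LEVELS = ("C_e", "C_m", "C_h")
COMPLEXITY_BLOCKS = {"C_e": 7, "C_m": 10, "C_h": 18}
BLOCKS_TO_COMPLEXITY = {v: k for k, v in COMPLEXITY_BLOCKS.items()}

_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


def proper_lattice_rotations() -> list[np.ndarray]:
    """The 24 rotation matrices of the proper cubic symmetry group.

    Signed permutation matrices with determinant +1.
    """
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    assert len(mats) == 24
    return mats


_ROTATIONS_24 = proper_lattice_rotations()


def _as_cells(cells) -> frozenset[tuple[int, int, int]]:
    out = frozenset(tuple(int(c) for c in cell) for cell in cells)
    if not out:
        raise InvalidInputError("cell set must be non-empty")
    if any(len(c) != 3 for c in out):
        raise InvalidInputError("cells must be integer 3-tuples")
    return out


def _is_connected(cells: frozenset[tuple[int, int, int]]) -> bool:
    start = next(iter(cells))
    seen = {start}
    frontier = [start]
    while frontier:
        cx, cy, cz = frontier.pop()
        for dx, dy, dz in _FACE_NEIGHBORS:
            nb = (cx + dx, cy + dy, cz + dz)
            if nb in cells and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return len(seen) == len(cells)


def canonical_form(cells) -> tuple[tuple[int, int, int], ...]:
    """Deterministic canonical representative of a polycube.

    Over all 24 proper lattice rotations, rotate, translate so the minimum
    coordinate per axis is zero, sort, and keep the lexicographically
    smallest cell list.  Idempotent and invariant under proper rotation.
    """
    cs = _as_cells(cells)
    if not _is_connected(cs):
        raise InvalidInputError("cells must be 6-connected (face adjacency)")
    pts = np.array(sorted(cs), dtype=int)
    best = None
    for rot in _ROTATIONS_24:
        rotated = pts @ rot.T
        rotated = rotated - rotated.min(axis=0)
        cand = tuple(sorted(map(tuple, rotated.tolist())))
        if best is None or cand < best:
            best = cand
    return best


@dataclass(frozen=True)
class PolycubeObject:
    """A block-built stimulus: lattice cells plus a physical cell size."""

    cells: frozenset
    cell_size: float = 0.03

    def __post_init__(self):
        object.__setattr__(self, "cells", _as_cells(self.cells))
        if not _is_connected(self.cells):
            raise InvalidInputError("polycube cells must be 6-connected")
        if self.cell_size <= 0:
            raise InvalidInputError("cell_size must be positive")

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def complexity(self) -> str | None:
        """C_e / C_m / C_h for the standard block counts, else None."""
        return BLOCKS_TO_COMPLEXITY.get(self.n)

    def cell_centers(self) -> np.ndarray:
        """Cell centers in the model frame, anchored at the bottom face.

        Model frame: x/y centered on the bounding box, z = 0 at the bottom
        of the lowest cell (the post-top mount plane).
        """
        pts = np.array(sorted(self.cells), dtype=float)
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        anchor = np.array([(lo[0] + hi[0] + 1.0) / 2.0, (lo[1] + hi[1] + 1.0) / 2.0, lo[2]])
        return (pts + 0.5 - anchor) * self.cell_size

    def bounding_box_center(self) -> np.ndarray:
        pts = np.array(sorted(self.cells), dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        half_height = (hi[2] + 1.0 - lo[2]) / 2.0
        return np.array([0.0, 0.0, half_height * self.cell_size])

    def half_diagonal(self) -> float:
        pts = np.array(sorted(self.cells), dtype=float)
        ext = (pts.max(axis=0) - pts.min(axis=0) + 1.0) * self.cell_size
        return float(np.linalg.norm(ext) / 2.0)


def are_congruent(a: PolycubeObject, b: PolycubeObject) -> bool:
    """True iff the two polycubes match under some proper rotation."""
    if a.n != b.n:
        return False
    return canonical_form(a.cells) == canonical_form(b.cells)


@dataclass
class ObjectInstance:
    """A posed stimulus: pose.position is the post-top mount point."""

    model: PolycubeObject
    pose: Pose6DOF
    bounding_radius: float = field(default=0.0)

    def __post_init__(self):
        min_radius = self.model.half_diagonal()
        if self.bounding_radius <= 0.0:
            self.bounding_radius = min_radius
        elif self.bounding_radius < min_radius - 1e-12:
            raise InvalidInputError(
                f"bounding_radius {self.bounding_radius} smaller than half diagonal {min_radius}"
            )

    def center(self) -> np.ndarray:
        """World center of the bounding sphere (rotated bbox center + mount)."""
        return self.pose.position + quat_rotate(self.pose.orientation, self.model.bounding_box_center())

    def world_cell_centers(self) -> np.ndarray:
        return self.pose.position + quat_rotate(self.pose.orientation, self.model.cell_centers())


def orientation_difference(a: ObjectInstance, b: ObjectInstance) -> float:
    """Geodesic angle in degrees between the two instance orientations."""
    return angular_difference(a.pose.orientation, b.pose.orientation)


def generate_random_polycube(
    n: int,
    rng: np.random.Generator,
    cell_size: float = 0.03,
    max_extent_cells: tuple[int, int, int] | None = None,
) -> PolycubeObject:
    """Grow a connected polycube of exactly ``n`` cells by uniform random
    face-adjacent accretion.  Reproducible for a given generator state.

    ``max_extent_cells`` optionally bounds the sorted bounding-box extents
    (in cells), keeping the object inside a physical envelope the way the
    real stimuli share one regardless of block count.
    """
    if n < 1:
        raise InvalidInputError("block count must be >= 1")
    limit = tuple(sorted(max_extent_cells)) if max_extent_cells else None
    if limit is not None and limit[0] * limit[1] * limit[2] < n:
        raise InvalidInputError("extent envelope too small for the block count")
    for _ in range(200):
        cells = {(0, 0, 0)}
        while len(cells) < n:
            frontier = sorted(
                {
                    (cx + dx, cy + dy, cz + dz)
                    for (cx, cy, cz) in cells
                    for dx, dy, dz in _FACE_NEIGHBORS
                }
                - cells
            )
            if limit is not None:
                frontier = [c for c in frontier if _fits(cells | {c}, limit)]
            if not frontier:
                break  # boxed in: restart the growth
            cells.add(frontier[rng.integers(len(frontier))])
        if len(cells) == n:
            return PolycubeObject(cells=frozenset(cells), cell_size=cell_size)
    raise GenerationError("could not grow a polycube inside the extent envelope")


def _fits(cells, limit: tuple[int, int, int]) -> bool:
    pts = np.array(list(cells))
    ext = tuple(sorted((pts.max(axis=0) - pts.min(axis=0) + 1).tolist()))
    return all(e <= m for e, m in zip(ext, limit))


DEFAULT_POST_POSITIONS = (
    np.array([1.5, 2.8, 1.2]),
    np.array([1.9, 2.8, 1.2]),
)
"""Default post-top mount points: posts 0.4 m apart at 1.2 m height."""

#: lattice cell size per complexity level.  The physical stimuli share a
#: similar overall envelope (~12 x 14 x 18 cm) across complexity, so fewer
#: blocks means larger blocks.
DEFAULT_CELL_SIZES = {"C_e": 0.06, "C_m": 0.045, "C_h": 0.035}

#: sorted bounding-box limits (in cells) per complexity; together with the
#: cell sizes these keep every stimulus inside the shared envelope.
DEFAULT_EXTENT_CELLS = {"C_e": (2, 2, 3), "C_m": (3, 3, 4), "C_h": (3, 4, 5)}

#: bounding spheres are floored at 10 cm so every stimulus subtends a
#: usable angular radius from any vantage point in the arena.
MIN_BOUNDING_RADIUS = 0.10


def make_stimulus_pair(
    complexity: str,
    same: bool,
    orientation_diff_deg: float,
    rng: np.random.Generator,
    *,
    positions=None,
    cell_size: float | None = None,
    max_tries: int = 200,
) -> tuple[ObjectInstance, ObjectInstance]:
    """Build a posed stimulus pair for one trial.

    ``same`` pairs share one model; different pairs are re-drawn until they
    fail the congruence test.  The second pose is the first rotated by the
    requested angle about the post (vertical) axis, so the measured
    orientation difference equals the request exactly.
    """
    if complexity not in COMPLEXITY_BLOCKS:
        raise InvalidInputError(f"unknown complexity level {complexity!r}")
    if not (0.0 <= orientation_diff_deg <= 180.0):
        raise InvalidInputError("orientation difference must be in [0, 180] degrees")
    if positions is None:
        positions = DEFAULT_POST_POSITIONS
    if cell_size is None:
        cell_size = DEFAULT_CELL_SIZES[complexity]
    extent = DEFAULT_EXTENT_CELLS[complexity]
    n = COMPLEXITY_BLOCKS[complexity]
    model_a = generate_random_polycube(n, rng, cell_size, extent)
    if same:
        model_b = model_a
    else:
        for _ in range(max_tries):
            model_b = generate_random_polycube(n, rng, cell_size, extent)
            if not are_congruent(model_a, model_b):
                break
        else:  # pragma: no cover - probability ~0 for n >= 7
            raise GenerationError(
                f"could not draw a non-congruent {complexity} pair in {max_tries} tries"
            )
    yaw_a = float(rng.uniform(0.0, 360.0))
    q_a = quat_from_yaw(yaw_a)
    q_b = quat_multiply(quat_from_yaw(orientation_diff_deg), q_a)
    r_a = max(model_a.half_diagonal(), MIN_BOUNDING_RADIUS)
    r_b = max(model_b.half_diagonal(), MIN_BOUNDING_RADIUS)
    inst_a = ObjectInstance(model_a, Pose6DOF(0.0, np.asarray(positions[0], float), q_a), r_a)
    inst_b = ObjectInstance(model_b, Pose6DOF(0.0, np.asarray(positions[1], float), q_b), r_b)
    return inst_a, inst_b


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def polycube_to_dict(obj: PolycubeObject) -> dict:
    return {
        "cells": [list(c) for c in sorted(obj.cells)],
        "cell_size_m": obj.cell_size,
        "complexity": obj.complexity,
    }


def polycube_from_dict(d: dict) -> PolycubeObject:
    return PolycubeObject(cells=frozenset(tuple(c) for c in d["cells"]), cell_size=d["cell_size_m"])


def instance_to_dict(inst: ObjectInstance) -> dict:
    d = polycube_to_dict(inst.model)
    d["pose"] = {
        "t": inst.pose.t,
        "position": inst.pose.position.tolist(),
        "quaternion": inst.pose.orientation.tolist(),
    }
    d["bounding_radius_m"] = inst.bounding_radius
    return d


def instance_from_dict(d: dict) -> ObjectInstance:
    pose = d["pose"]
    return ObjectInstance(
        model=polycube_from_dict(d),
        pose=Pose6DOF(pose["t"], np.array(pose["position"]), np.array(pose["quaternion"])),
        bounding_radius=d.get("bounding_radius_m", 0.0),
    )


def save_instances(path, instances) -> None:
    with open(path, "w") as fh:
        json.dump([instance_to_dict(i) for i in instances], fh, indent=1)


def load_instances(path) -> list[ObjectInstance]:
    with open(path) as fh:
        return [instance_from_dict(d) for d in json.load(fh)]
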