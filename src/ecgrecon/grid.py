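"""Chest electrode grid: geometry, combination families, chest-lead algebra.

The sensing array is a 7-column x 5-row lattice of 35 electrodes with 5 cm
spacing laid on the anterior chest. Electrodes are numbered column-major:
ids 1..5 run down the leftmost column, 6..10 down the next, and so on, which
puts electrode 16 at the top of the central (4th) column — the
clavicle–sternum junction that anchors the array on the subject.

A candidate patch is an unordered set of four electrodes. Three bipolar
"chest leads" (CLs) are formed by subtracting the lowest-numbered electrode's
potential from each of the other three; any fixed reference choice spans the
same 3-dimensional lead space, so downstream regression metrics do not
depend on it.

Combination families:

* ``free``      — all C(35, 4) = 52,360 unordered quadruples.
* ``square5``   — 5 cm x 5 cm axis-aligned squares (24 placements).
* ``square10``  — 10 cm x 10 cm axis-aligned squares (15 placements).
* ``triangle``  — right-angled triangles inscribed in a 10 cm x 10 cm area:
  the square's centre electrode plus three of its four corners, giving four
  orientations per placement (60 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GridLayout",
    "ElectrodeCombination",
    "ChestLeadTriplet",
    "enumerate_all",
    "enumerate_squares",
    "enumerate_triangles",
    "enumerate_family",
    "compute_chest_leads",
    "shift_combination",
    "combinations_to_frame",
]

SHAPE_TAGS = ("free", "square5", "square10", "triangle")
DIRECTIONS = ("up", "down", "left", "right")
# "up" is toward the clavicle (row 1); lattice steps in (col, row).
_STEPS = {"up": (0, -1), "down": (0, 1), "left": (-1, 0), "right": (1, 0)}


@dataclass(frozen=True)
class GridLayout:
    """Logical lattice and physical geometry of the chest electrode array."""

    n_cols: int = 7
    n_rows: int = 5
    spacing_cm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one column and one row")
        if self.spacing_cm <= 0:
            raise ValueError("electrode spacing must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_cols * self.n_rows

    def position(self, electrode_id: int) -> tuple[int, int]:
        """Map an electrode id to its 1-based (col, row) lattice cell."""
        if not 1 <= electrode_id <= self.n_electrodes:
            raise ValueError(
                f"electrode id {electrode_id} outside 1..{self.n_electrodes}"
            )
        col = (electrode_id - 1) // self.n_rows + 1
        row = (electrode_id - 1) % self.n_rows + 1
        return col, row

    def electrode_id(self, col: int, row: int) -> int:
        """Inverse of :meth:`position`."""
        if not (1 <= col <= self.n_cols and 1 <= row <= self.n_rows):
            raise ValueError(f"cell ({col}, {row}) outside the lattice")
        return (col - 1) * self.n_rows + row

    def xy_cm(self, electrode_id: int) -> tuple[float, float]:
        """Planar coordinates (cm): x grows rightward, y drops caudally."""
        col, row = self.position(electrode_id)
        return (col - 1) * self.spacing_cm, -(row - 1) * self.spacing_cm

    def ids(self) -> range:
        return range(1, self.n_electrodes + 1)


@dataclass(frozen=True)
class ElectrodeCombination:
    """Unordered 4-electrode subset with an optional shape/orientation tag."""

    ids: tuple[int, int, int, int]
    shape_tag: str = "free"
    orientation: int | None = None

    def __post_init__(self) -> None:
        ids = tuple(sorted(int(i) for i in self.ids))
        if len(ids) != 4 or len(set(ids)) != 4:
            raise ValueError("a combination needs exactly 4 distinct electrode ids")
        if any(i < 1 for i in ids):
            raise ValueError("electrode ids are 1-based positive integers")
        if self.shape_tag not in SHAPE_TAGS:
            raise ValueError(f"unknown shape tag {self.shape_tag!r}")
        if self.shape_tag == "triangle":
            if self.orientation not in (1, 2, 3, 4):
                raise ValueError("triangle combinations carry orientation 1..4")
        elif self.orientation is not None:
            raise ValueError("orientation applies to triangle combinations only")
        object.__setattr__(self, "ids", ids)

    @property
    def reference_id(self) -> int:
        """Common reference for chest-lead subtraction: the lowest id."""
        return self.ids[0]

    def key(self) -> tuple[int, int, int, int]:
        return self.ids


@dataclass(frozen=True)
class ChestLeadTriplet:
    """Three bipolar chest leads derived from a 4-electrode combination.

    ``cl`` is a (3, T) array in uV: each row is one non-reference electrode's
    potential minus the reference electrode's potential.
    """

    cl: np.ndarray
    source_combination: ElectrodeCombination
    reference_id: int

    def as_features(self) -> np.ndarray:
        """(T, 3) sample-major view for estimator APIs."""
        return self.cl.T


def enumerate_all(grid: GridLayout | None = None) -> list[ElectrodeCombination]:
    """All unordered 4-subsets of the grid (52,360 on the full 7x5 array)."""
    grid = grid or GridLayout()
    return [
        ElectrodeCombination(ids)
        for ids in combinations(grid.ids(), 4)
    ]


def _square_placements(grid: GridLayout, steps: int) -> Iterator[tuple[int, int]]:
    for col in range(1, grid.n_cols - steps + 1):
        for row in range(1, grid.n_rows - steps + 1):
            yield col, row


def enumerate_squares(
    side_cm: float, grid: GridLayout | None = None
) -> list[ElectrodeCombination]:
    """Axis-aligned squares with the given physical side length.

    The count is (n_cols - s)(n_rows - s) with s = side / spacing lattice
    steps: 24 for 5 cm and 15 for 10 cm squares on the full grid.
    """
    grid = grid or GridLayout()
    steps_f = side_cm / grid.spacing_cm
    steps = int(round(steps_f))
    if steps < 1 or abs(steps_f - steps) > 1e-9:
        raise ValueError(
            f"square side {side_cm} cm is not a positive multiple of the "
            f"{grid.spacing_cm} cm electrode spacing"
        )
    tag = f"square{int(round(side_cm))}"
    if tag not in SHAPE_TAGS:
        raise ValueError(f"unsupported square side {side_cm} cm (use 5 or 10)")
    out = []
    for col, row in _square_placements(grid, steps):
        ids = (
            grid.electrode_id(col, row),
            grid.electrode_id(col + steps, row),
            grid.electrode_id(col, row + steps),
            grid.electrode_id(col + steps, row + steps),
        )
        out.append(ElectrodeCombination(ids, shape_tag=tag))
    return out


def enumerate_triangles(grid: GridLayout | None = None) -> list[ElectrodeCombination]:
    """Right-angled triangles in a 10 cm x 10 cm area.

    For every 10x10 square placement: the centre electrode plus three of the
    four corners. Orientation k in 1..4 records which corner is omitted
    (1 = top-left, 2 = top-right, 3 = bottom-left, 4 = bottom-right), i.e.
    where the right angle opens. 5 x 3 x 4 = 60 placements on the full grid.
    """
    grid = grid or GridLayout()
    out = []
    for col, row in _square_placements(grid, 2):
        corners = (
            grid.electrode_id(col, row),
            grid.electrode_id(col + 2, row),
            grid.electrode_id(col, row + 2),
            grid.electrode_id(col + 2, row + 2),
        )
        center = grid.electrode_id(col + 1, row + 1)
        for k in range(4):
            ids = tuple(c for j, c in enumerate(corners) if j != k) + (center,)
            out.append(
                ElectrodeCombination(ids, shape_tag="triangle", orientation=k + 1)
            )
    return out


def enumerate_family(
    family: str, grid: GridLayout | None = None
) -> list[ElectrodeCombination]:
    """Dispatch on a shape-family name: free, square5, square10, triangle."""
    grid = grid or GridLayout()
    if family == "free":
        return enumerate_all(grid)
    if family == "square5":
        return enumerate_squares(5.0 * grid.spacing_cm / 5.0, grid)
    if family == "square10":
        return enumerate_squares(10.0 * grid.spacing_cm / 5.0, grid)
    if family == "triangle":
        return enumerate_triangles(grid)
    raise ValueError(f"unknown combination family {family!r}")


def compute_chest_leads(
    chest: np.ndarray | Mapping[int, np.ndarray],
    combination: ElectrodeCombination,
) -> ChestLeadTriplet:
    """Subtract the reference (lowest-id) electrode from the other three.

    ``chest`` is either a (35, T) array indexed by electrode id - 1 or a
    mapping from electrode id to a 1-D signal (uV).
    """

    def channel(eid: int) -> np.ndarray:
        if isinstance(chest, Mapping):
            return np.asarray(chest[eid], dtype=float)
        return np.asarray(chest[eid - 1], dtype=float)

    ref = combination.reference_id
    ref_sig = channel(ref)
    cl = np.stack([channel(eid) - ref_sig for eid in combination.ids[1:]])
    return ChestLeadTriplet(cl=cl, source_combination=combination, reference_id=ref)


def shift_combination(
    combination: ElectrodeCombination,
    direction: str,
    grid: GridLayout | None = None,
) -> ElectrodeCombination | None:
    """Translate every electrode one lattice step; None if any leaves the grid."""
    grid = grid or GridLayout()
    if direction not in _STEPS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    dc, dr = _STEPS[direction]
    new_ids = []
    for eid in combination.ids:
        col, row = grid.position(eid)
        col, row = col + dc, row + dr
        if not (1 <= col <= grid.n_cols and 1 <= row <= grid.n_rows):
            return None
        new_ids.append(grid.electrode_id(col, row))
    return ElectrodeCombination(
        tuple(new_ids),
        shape_tag=combination.shape_tag,
        orientation=combination.orientation,
    )


def combinations_to_frame(combos: Sequence[ElectrodeCombination]):
    """Serialize combinations to a DataFrame (CSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "e1": [c.ids[0] for c in combos],
            "e2": [c.ids[1] for c in combos],
            "e3": [c.ids[2] for c in combos],
            "e4": [c.ids[3] for c in combos],
            "shape_tag": [c.shape_tag for c in combos],
            "orientation": [c.orientation for c in combos],
        }
    )
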