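"""Domain types and geometry shared by every other module.

The simulated system is the basal layer of human epidermis, modelled as a
flat square culture dish populated by non-deformable spherical cells of
20 µm diameter.  Three cell types live on the dish: stem keratinocytes,
transit-amplifying (TA) keratinocytes and melanocytes.  All coordinates are
continuous 2-D positions in µm with the origin at a dish corner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_CELL_RADIUS = 10.0  # µm; 20 µm diameter spheres
CELL_DIAMETER = 2.0 * DEFAULT_CELL_RADIUS


class CellType(enum.IntEnum):
    """The three agent types of the basal-layer model."""

    STEM_KERATINOCYTE = 0
    TA_KERATINOCYTE = 1
    MELANOCYTE = 2


@dataclass
class Cell:
    """One agent: type, position, signal compartment levels and cycle state.

    ``level_R`` is the amount of the melanocyte-produced repellent substance
    held in this cell's compartment; ``level_A`` the keratinocyte-produced
    attractant.  ``cycle_counter`` is the integer cell-cycle progress
    variable; ``divisions_done`` counts completed divisions (meaningful for
    TA keratinocytes, which divide a bounded number of times).
    """

    id: int
    type: CellType
    x: float
    y: float
    radius: float = DEFAULT_CELL_RADIUS
    level_R: float = 0.0
    level_A: float = 0.0
    cycle_counter: int = 0
    divisions_done: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"cell radius must be > 0, got {self.radius}")
        if self.level_R < 0 or self.level_A < 0:
            raise ValueError("signal levels must be >= 0")
        if self.cycle_counter < 0 or self.divisions_done < 0:
            raise ValueError("cycle counters must be >= 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class Dish:
    """The square virtual dish with an impenetrable wall.

    Observations are restricted to a centred square window set in from the
    walls by ``observation_margin`` to avoid boundary artifacts.
    """

    side: float = 400.0
    observation_margin: float = 50.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("dish side must be > 0")
        if not (0 <= 2 * self.observation_margin < self.side):
            raise ValueError("observation margin incompatible with dish side")

    @property
    def observation_side(self) -> float:
        return self.side - 2.0 * self.observation_margin


class Population:
    """Column-oriented storage for the whole cell population.

    The engine operates on parallel numpy arrays for speed; ``Cell`` records
    are views constructed on demand.  Arrays are kept the same length and
    rows correspond to single cells.
    """

    __slots__ = ("ids", "types", "xy", "radius", "level_R", "level_A",
                 "cycle", "divisions")

    def __init__(self, ids, types, xy, radius, level_R, level_A, cycle,
                 divisions) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.types = np.asarray(types, dtype=np.int8)
        self.xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
        self.radius = np.asarray(radius, dtype=np.float64)
        self.level_R = np.asarray(level_R, dtype=np.float64)
        self.level_A = np.asarray(level_A, dtype=np.float64)
        self.cycle = np.asarray(cycle, dtype=np.int64)
        self.divisions = np.asarray(divisions, dtype=np.int64)
        n = len(self.ids)
        for name in self.__slots__:
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("cell ids must be unique")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_cells(cls, cells: Iterable[Cell]) -> "Population":
        cells = list(cells)
        return cls(
            ids=[c.id for c in cells],
            types=[int(c.type) for c in cells],
            xy=np.array([[c.x, c.y] for c in cells]).reshape(-1, 2),
            radius=[c.radius for c in cells],
            level_R=[c.level_R for c in cells],
            level_A=[c.level_A for c in cells],
            cycle=[c.cycle_counter for c in cells],
            divisions=[c.divisions_done for c in cells],
        )

    @classmethod
    def empty(cls) -> "Population":
        z = np.zeros(0)
        return cls(z, z, z.reshape(0, 2), z, z, z, z, z)

    def to_cells(self) -> list[Cell]:
        return [
            Cell(
                id=int(self.ids[i]),
                type=CellType(int(self.types[i])),
                x=float(self.xy[i, 0]),
                y=float(self.xy[i, 1]),
                radius=float(self.radius[i]),
                level_R=float(self.level_R[i]),
                level_A=float(self.level_A[i]),
                cycle_counter=int(self.cycle[i]),
                divisions_done=int(self.divisions[i]),
            )
            for i in range(len(self))
        ]

    # -- helpers -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def copy(self) -> "Population":
        return Population(*(getattr(self, s).copy() for s in self.__slots__))

    def take(self, index: np.ndarray) -> "Population":
        return Population(*(getattr(self, s)[index] for s in self.__slots__))

    def sort_by_id(self) -> "Population":
        order = np.argsort(self.ids, kind="stable")
        return self.take(order)

    def is_mel(self) -> np.ndarray:
        return self.types == int(CellType.MELANOCYTE)

    def is_keratinocyte(self) -> np.ndarray:
        return self.types != int(CellType.MELANOCYTE)

    def next_id(self) -> int:
        return int(self.ids.max()) + 1 if len(self) else 0


@dataclass
class SimulationState:
    """Iteration counter, cell population and the run's RNG stream.

    One iteration corresponds to 30 simulated minutes.  Advancing a state
    with identical parameters and RNG state is bit-reproducible.
    """

    iteration: int
    population: Population
    rng: np.random.Generator
    dish: Dish = field(default_factory=Dish)

    @property
    def cells(self) -> list[Cell]:
        return self.population.to_cells()

    @classmethod
    def from_cells(cls, cells: Sequence[Cell], seed: int | None = 0,
                   dish: Dish | None = None,
                   iteration: int = 0) -> "SimulationState":
        return cls(iteration=iteration,
                   population=Population.from_cells(cells),
                   rng=np.random.default_rng(seed),
                   dish=dish if dish is not None else Dish())


# ---------------------------------------------------------------------------
# geometry / neighbour operations
# ---------------------------------------------------------------------------

def neighbors_within(cells: Sequence[Cell], center: Cell,
                     radius: float) -> list[Cell]:
    """All cells within ``radius`` µm (center-to-center, inclusive) of
    ``center``, excluding ``center`` itself.

    The relation is symmetric and irreflexive.  Distances are compared with
    ``<=`` so cells at exactly the threshold distance count as neighbours.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    cells = list(cells)
    if not cells:
        return []
    xy = np.array([[c.x, c.y] for c in cells])
    tree = cKDTree(xy)
    idx = tree.query_ball_point([center.x, center.y], r=radius)
    return [cells[i] for i in sorted(idx) if cells[i].id != center.id]


def neighbor_pairs(xy: np.ndarray, radius: float) -> np.ndarray:
    """Index pairs (i, j), i < j, with center distance <= radius.

    Returns an (m, 2) int array; empty (0, 2) when no pair qualifies.
    """
    if len(xy) < 2:
        return np.zeros((0, 2), dtype=np.int64)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if pairs.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    return pairs.astype(np.int64)


def in_observation_area(cell: Cell | np.ndarray, dish: Dish):
    """Whether a position lies in the central observation window.

    Accepts a single ``Cell`` (returns bool) or an (n, 2) position array
    (returns a boolean mask).  The window boundary is inclusive.
    """
    lo = dish.observation_margin
    hi = dish.side - dish.observation_margin
    if isinstance(cell, Cell):
        return bool(lo <= cell.x <= hi and lo <= cell.y <= hi)
    xy = np.asarray(cell, dtype=float).reshape(-1, 2)
    return (xy[:, 0] >= lo) & (xy[:, 0] <= hi) & \
           (xy[:, 1] >= lo) & (xy[:, 1] <= hi)
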