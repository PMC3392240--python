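"""Cell movement: melanocyte chemotaxis, TA random walk, overlap repulsion,
adhesion and dish-wall constraints.

Melanocyte migration follows a deliberately simple two-neighbour rule: the
cell looks at the guidance-substance levels of its neighbours, identifies
the neighbour with the strongest and the neighbour with the weakest signal,
and moves along the sum of a unit vector toward the maximum and a unit
vector away from the minimum, scaled by the level difference (attractant
mode; the repellent mode is the same construction with opposite
orientation).  In shallow gradients the extremes are noisy, so the walk is
only weakly biased — a weighted random walk.

Overlaps created by division and migration are resolved by position-based
relaxation: overlapping pairs are pushed apart along their centre line by a
displacement proportional to the circle–circle intersection area, in
synchronous (Jacobi) sweeps so the result is independent of cell storage
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Dish, neighbor_pairs


@dataclass(frozen=True)
class MechanicsParams:
    """Migration and contact-mechanics parameters.

    migration_gain
        µm of displacement per unit guidance-signal difference.
    max_step
        Cap on a single iteration's chemotactic displacement, µm
        (default 8 µm per 30-min iteration; rarely binding, the step is
        normally set by the signal contrast itself).
    ta_random_step
        Magnitude of the TA keratinocyte random-walk step, µm/iteration.
    repulsion_gain
        µm of pair separation per µm² of circle overlap area.
    adhesion_range / adhesion_gain
        Cell–cell attraction acts when the surface gap is in
        (0, adhesion_range] µm, pulling the pair together by
        adhesion_gain × (gap / adhesion_range) µm.
    substrate_damping
        Multiplier in (0, 1] applied to every displacement vector; the
        monolayer representation of cell–substrate bonds.
    relaxation_iterations
        Maximum synchronous overlap-resolution sweeps per engine step.
    """

    migration_gain: float = 1.0
    max_step: float = 8.0
    ta_random_step: float = 0.5
    repulsion_gain: float = 0.2
    adhesion_range: float = 10.0
    adhesion_gain: float = 0.2
    substrate_damping: float = 1.0
    relaxation_iterations: int = 8
    overlap_tolerance: float = 0.1  # µm residual depth at which to stop

    def __post_init__(self) -> None:
        for name in ("migration_gain", "ta_random_step", "repulsion_gain",
                     "adhesion_range", "adhesion_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if not (0 < self.substrate_damping <= 1):
            raise ValueError("substrate_damping must be in (0, 1]")
        if self.relaxation_iterations < 1:
            raise ValueError("relaxation_iterations must be >= 1")


# ---------------------------------------------------------------------------
# chemotaxis
# ---------------------------------------------------------------------------

def chemotaxis_vector(position: np.ndarray,
                      neighbor_positions: np.ndarray,
                      neighbor_levels: np.ndarray,
                      mode: str,
                      params: MechanicsParams,
                      neighbor_ids: np.ndarray | None = None) -> np.ndarray:
    """Migration vector from the two-extreme-neighbour rule.

    With u_max / u_min the unit vectors from the cell toward the neighbours
    carrying the highest and lowest guidance level and Δ their level
    difference: attract mode gives migration_gain·Δ·(u_max − u_min),
    repel mode the negation (moving down the gradient).  The magnitude is
    capped at ``max_step``.  An empty neighbour list or a flat field
    (Δ = 0) gives the zero vector.  Level ties are broken toward the lowest
    cell id when ids are supplied, else the lowest list index.
    """
    if mode not in ("attract", "repel"):
        raise ValueError("mode must be 'attract' or 'repel'")
    neighbor_positions = np.asarray(neighbor_positions, float).reshape(-1, 2)
    neighbor_levels = np.asarray(neighbor_levels, float)
    if len(neighbor_positions) == 0:
        return np.zeros(2)
    if neighbor_ids is None:
        neighbor_ids = np.arange(len(neighbor_levels))
    # among level ties: lowest id wins for both extremes
    i_min = np.lexsort((neighbor_ids, neighbor_levels))[0]
    i_max = np.lexsort((-np.asarray(neighbor_ids), neighbor_levels))[-1]
    delta = neighbor_levels[i_max] - neighbor_levels[i_min]
    if delta <= 0:
        return np.zeros(2)

    def unit(i):
        v = neighbor_positions[i] - np.asarray(position, float)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else np.zeros(2)

    v = params.migration_gain * delta * (unit(i_max) - unit(i_min))
    if mode == "repel":
        v = -v
    nrm = np.linalg.norm(v)
    if nrm > params.max_step:
        v *= params.max_step / nrm
    return v


def ta_random_step(params: MechanicsParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform-direction step of fixed magnitude for a TA keratinocyte.

    Stem keratinocytes and melanocytes never receive this step: stems are
    tightly substrate-bound and stationary except for mechanical pushing,
    and melanocytes move chemotactically.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return params.ta_random_step * np.array([np.cos(phi), np.sin(phi)])


# ---------------------------------------------------------------------------
# contact mechanics
# ---------------------------------------------------------------------------

def lens_area(d: np.ndarray, r: float) -> np.ndarray:
    """Intersection area of two circles of equal radius r at centre
    distance d (the symmetric lens):  2r²·acos(d/2r) − (d/2)·√(4r² − d²).
    Zero at and beyond tangency (d ≥ 2r)."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    inside = d < 2.0 * r
    di = d[inside]
    out[inside] = (2.0 * r * r * np.arccos(di / (2.0 * r))
                   - 0.5 * di * np.sqrt(4.0 * r * r - di * di))
    return out


def resolve_overlaps(xy: np.ndarray, radius: np.ndarray | float,
                     params: MechanicsParams,
                     rng: np.random.Generator | None = None,
                     dish: Dish | None = None) -> np.ndarray:
    """Push overlapping cells apart by synchronous relaxation sweeps.

    Each overlapping pair receives a separation proportional to the
    circle–circle intersection area (repulsion_gain × area, but never more
    than would separate the pair past tangency), split equally and applied
    along the centre line.  Sweeps are synchronous — displacements computed
    from the same snapshot, then applied together — so the outcome does not
    depend on cell storage order.  Stops after ``relaxation_iterations``
    sweeps or when the deepest residual overlap is below
    ``overlap_tolerance``.  Coincident centres are separated along a random
    direction drawn from ``rng``.
    """
    xy = np.array(xy, dtype=float).reshape(-1, 2)
    r = float(np.max(radius)) if np.ndim(radius) else float(radius)
    for _ in range(params.relaxation_iterations):
        pairs = neighbor_pairs(xy, 2.0 * r)
        if len(pairs) == 0:
            break
        diff = xy[pairs[:, 1]] - xy[pairs[:, 0]]
        dist = np.linalg.norm(diff, axis=1)
        depth = 2.0 * r - dist
        active = depth > 0
        if not np.any(active) or depth.max() <= params.overlap_tolerance:
            break
        pairs, diff, dist = pairs[active], diff[active], dist[active]
        area = lens_area(dist, r)
        # half-depth cap: full-tangency Jacobi pushes overshoot when a cell
        # has several overlapping neighbours, so sweeps would oscillate
        sep = np.minimum(params.repulsion_gain * area, 0.5 * (2.0 * r - dist))
        dirs = np.zeros_like(diff)
        pos = dist > 0
        dirs[pos] = diff[pos] / dist[pos, None]
        if np.any(~pos):
            k = int((~pos).sum())
            phi = (rng.uniform(0, 2 * np.pi, size=k) if rng is not None
                   else np.zeros(k))
            dirs[~pos] = np.column_stack([np.cos(phi), np.sin(phi)])
            sep = np.where(pos, sep, 2.0 * r)
        move = 0.5 * sep[:, None] * dirs
        delta = np.zeros_like(xy)
        np.add.at(delta, pairs[:, 0], -move)
        np.add.at(delta, pairs[:, 1], move)
        xy += delta
        if dish is not None:
            xy = clamp_to_dish(xy, dish, r)
    return xy


def apply_adhesion(xy: np.ndarray, radius: float,
                   params: MechanicsParams) -> np.ndarray:
    """Pull near-contact pairs together along the centre line.

    Pairs with surface gap in (0, adhesion_range] approach by
    adhesion_gain × (gap / adhesion_range) µm shared equally, capped so a
    single application never moves a pair past tangency.  Touching or
    overlapping pairs (gap ≤ 0) are untouched.
    """
    xy = np.array(xy, dtype=float).reshape(-1, 2)
    r = float(radius)
    pairs = neighbor_pairs(xy, 2.0 * r + params.adhesion_range)
    if len(pairs) == 0:
        return xy
    diff = xy[pairs[:, 1]] - xy[pairs[:, 0]]
    dist = np.linalg.norm(diff, axis=1)
    gap = dist - 2.0 * r
    active = (gap > 0) & (gap <= params.adhesion_range)
    if not np.any(active):
        return xy
    pairs, diff, dist, gap = pairs[active], diff[active], dist[active], gap[active]
    pull = np.minimum(params.adhesion_gain * gap / params.adhesion_range, gap)
    dirs = diff / dist[:, None]
    move = 0.5 * pull[:, None] * dirs
    delta = np.zeros_like(xy)
    np.add.at(delta, pairs[:, 0], move)
    np.add.at(delta, pairs[:, 1], -move)
    return xy + delta


def clamp_to_dish(xy: np.ndarray, dish: Dish,
                  radius: float) -> np.ndarray:
    """Clip positions so every cell body stays inside the dish walls.

    Each coordinate is clipped to [radius, side − radius]; idempotent.
    """
    xy = np.asarray(xy, dtype=float)
    return np.clip(xy, radius, dish.side - radius)
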