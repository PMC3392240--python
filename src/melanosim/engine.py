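"""Synchronous phase scheduler, scenario initialisation and mechanism
selection.

Each iteration (30 simulated minutes) executes a fixed phase sequence with
a full barrier between phases — no cell reads another cell's phase-k output
before every cell has finished phase k.  The original model ran on an
asynchronous message-passing framework; here the message lists are replaced
by synchronous double-buffered array updates with identical observable
behaviour.  All randomness comes from a single per-run generator consumed
in a fixed phase / cell-id order, and the population is canonically sorted
by cell id at the start of every step, so results are independent of
storage order and bit-reproducible per seed.

Phase order: signal production → outflux → influx → degradation → cycle
advance → melanocyte death → division → differentiation (realised inside
stem division) → migration → overlap resolution + adhesion + wall clamp →
stratification removal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import dynamics, fixtures, metrics
from .core import (Cell, CellType, DEFAULT_CELL_RADIUS, Dish, Population,
                   SimulationState, neighbor_pairs)
from .dynamics import CycleParams
from .mechanics import (MechanicsParams, chemotaxis_vector, clamp_to_dish,
                        apply_adhesion, resolve_overlaps)
from .signaling import SignalParams, diffusion_step_levels, produce_A_continuous

HEX_PACKING_FRACTION = np.pi / (2.0 * np.sqrt(3.0))  # densest disc packing


class Mechanism(str, enum.Enum):
    """The three chemotactic guidance hypotheses.

    REPELLENT_R: melanocytes secrete a repellent R and move down its
    gradient.  ATTRACTANT_A_BINARY: keratinocytes without melanocyte
    contact secrete an attractant A at a constant rate.
    ATTRACTANT_A_CONTINUOUS: keratinocytes secrete A at a rate repressed by
    the local level of R, which then serves purely as a distance measure to
    the surrounding melanocytes, not as a migration cue.
    """

    REPELLENT_R = "R"
    ATTRACTANT_A_BINARY = "A-bin"
    ATTRACTANT_A_CONTINUOUS = "A-cont"

    @property
    def uses_R(self) -> bool:
        return self in (Mechanism.REPELLENT_R,
                        Mechanism.ATTRACTANT_A_CONTINUOUS)

    @property
    def uses_A(self) -> bool:
        return self != Mechanism.REPELLENT_R

    @property
    def cue(self) -> str:
        """Which substance guides melanocyte migration and fate."""
        return "R" if self == Mechanism.REPELLENT_R else "A"

    @property
    def migration_mode(self) -> str:
        return "repel" if self == Mechanism.REPELLENT_R else "attract"


class ScenarioKind(str, enum.Enum):
    RANDOM_SEEDING = "random"
    RIM_RESTRICTED = "rim"


@dataclass(frozen=True)
class Scenario:
    """Initial layout and special-casing of a run.

    RANDOM_SEEDING scatters ``initial_cell_count`` cells uniformly (then
    relaxes overlaps); each is a melanocyte with probability
    ``initial_melanocyte_fraction``, otherwise a stem keratinocyte with
    probability ``p_stem`` else a TA keratinocyte.  RIM_RESTRICTED pins
    melanocytes in a ring against the wall with keratinocytes hex-packed
    inside and freezes all cell dynamics (signals only) — the configuration
    used to visualise the global signal gradients.
    """

    kind: ScenarioKind = ScenarioKind.RANDOM_SEEDING
    initial_cell_count: int = 150
    initial_melanocyte_fraction: float = 0.10
    p_stem: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.initial_melanocyte_fraction <= 1.0):
            raise ValueError("initial_melanocyte_fraction must be in [0, 1]")
        if self.initial_cell_count < 0:
            raise ValueError("initial_cell_count must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Everything that parameterises a run, gathered by concern."""

    dish: Dish = field(default_factory=Dish)
    signal: SignalParams = field(default_factory=SignalParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    signals_only: bool = False  # freeze all cell dynamics (rim / calibration)
    neighbor_count_inclusive: bool = False  # ">= 3" metric variant


class InitializationError(RuntimeError):
    pass


def _relax_hard(xy: np.ndarray, r: float, dish: Dish,
                rng: np.random.Generator, sweeps: int = 400,
                tol: float = 0.5, jitter: float = 0.05) -> np.ndarray:
    """Initial-seeding relaxation: synchronous sweeps separating each
    overlapping pair by a fixed fraction of its overlap depth, plus a tiny
    positional jitter that anneals locally jammed clusters.  Stronger than
    the in-run area-proportional repulsion, which is tuned for the shallow
    overlaps of ordinary dynamics, not for random seeding at high
    coverage."""
    xy = np.array(xy, dtype=float).reshape(-1, 2)
    for _ in range(sweeps):
        pairs = neighbor_pairs(xy, 2.0 * r)
        if len(pairs) == 0:
            break
        diff = xy[pairs[:, 1]] - xy[pairs[:, 0]]
        dist = np.linalg.norm(diff, axis=1)
        depth = 2.0 * r - dist
        if depth.max() <= tol:
            break
        dirs = np.zeros_like(diff)
        pos = dist > 0
        dirs[pos] = diff[pos] / dist[pos, None]
        coinc = ~pos
        if coinc.any():
            phi = rng.uniform(0, 2 * np.pi, size=int(coinc.sum()))
            dirs[coinc] = np.column_stack([np.cos(phi), np.sin(phi)])
        move = 0.3 * depth[:, None] * dirs
        delta = np.zeros_like(xy)
        np.add.at(delta, pairs[:, 0], -move)
        np.add.at(delta, pairs[:, 1], move)
        if jitter > 0:
            delta += rng.normal(0.0, jitter, size=xy.shape)
        xy = np.clip(xy + delta, r, dish.side - r)
    return xy


def init_state(params: SimulationParams, scenario: Scenario,
               seed: int) -> SimulationState:
    """Build the iteration-0 state for a scenario; identical inputs give a
    bit-identical state."""
    rng = np.random.default_rng(seed)
    dish = params.dish
    r = DEFAULT_CELL_RADIUS
    if scenario.kind == ScenarioKind.RIM_RESTRICTED:
        cells = fixtures.rim_layout(dish)
        pop = Population.from_cells(cells)
        return SimulationState(0, pop, rng, dish)

    n = scenario.initial_cell_count
    if n * np.pi * r * r > HEX_PACKING_FRACTION * dish.side ** 2:
        raise InitializationError(
            f"{n} cells of radius {r} cannot pack into the dish")
    xy = rng.uniform(r, dish.side - r, size=(n, 2))
    xy = _relax_hard(xy, r, dish, rng)
    if n >= 2:
        pairs = neighbor_pairs(xy, 2 * r)
        if len(pairs):
            dist = np.linalg.norm(xy[pairs[:, 1]] - xy[pairs[:, 0]], axis=1)
            if (2 * r - dist).max() > 2.0:
                raise InitializationError(
                    "initial density too high to relax overlaps")
    u = rng.uniform(size=n)
    types = np.full(n, int(CellType.TA_KERATINOCYTE), dtype=np.int8)
    mel = u < scenario.initial_melanocyte_fraction
    types[mel] = int(CellType.MELANOCYTE)
    stem = (~mel) & (rng.uniform(size=n) < scenario.p_stem)
    types[stem] = int(CellType.STEM_KERATINOCYTE)
    # desynchronise the cell cycle so divisions do not come in bursts
    thr = np.where(types == int(CellType.MELANOCYTE),
                   params.cycle.division_threshold_mel,
                   np.where(types == int(CellType.STEM_KERATINOCYTE),
                            params.cycle.division_threshold_stem,
                            params.cycle.division_threshold_ta))
    cycle = rng.integers(0, thr, size=n) if n else np.zeros(0, dtype=np.int64)
    # TA cells start mid-lifecycle, as in a growing culture; without this
    # no TA exhausts its budget for days and stratification cannot vent
    # the post-seeding division burst
    divisions = np.zeros(n, dtype=np.int64)
    ta = types == int(CellType.TA_KERATINOCYTE)
    divisions[ta] = rng.integers(0, params.cycle.max_ta_divisions + 1,
                                 size=int(ta.sum()))
    pop = Population(ids=np.arange(n), types=types, xy=xy,
                     radius=np.full(n, r), level_R=np.zeros(n),
                     level_A=np.zeros(n), cycle=cycle,
                     divisions=divisions)
    return SimulationState(0, pop, rng, dish)


# ---------------------------------------------------------------------------
# one iteration
# ---------------------------------------------------------------------------

def _chemotaxis_bulk(pop: Population, mel_idx: np.ndarray,
                     cue_levels: np.ndarray, pairs: np.ndarray,
                     mode: str, params: MechanicsParams) -> np.ndarray:
    """Chemotaxis displacement for every melanocyte at once.

    Equivalent to calling :func:`melanosim.mechanics.chemotaxis_vector` per
    melanocyte with its neighbour list; ties in the extreme levels break
    toward the lowest cell id.
    """
    disp = np.zeros((len(mel_idx), 2))
    if len(pairs) == 0 or len(mel_idx) == 0:
        return disp
    # directed edges (focal, neighbour) restricted to melanocyte focals
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    is_mel_focal = np.isin(src, mel_idx)
    src, dst = src[is_mel_focal], dst[is_mel_focal]
    if len(src) == 0:
        return disp
    lev = cue_levels[dst]
    nid = pop.ids[dst]
    # per focal cell: max level (ties -> lowest id), min level (ties -> lowest id)
    o_max = np.lexsort((-nid, lev, src))   # within focal: level asc, id desc
    o_min = np.lexsort((nid, lev, src))    # within focal: level asc, id asc
    s_max, s_min = src[o_max], src[o_min]
    last = np.flatnonzero(np.r_[s_max[1:] != s_max[:-1], True])
    first = np.flatnonzero(np.r_[True, s_min[1:] != s_min[:-1]])
    focal = s_max[last]
    jmax = dst[o_max][last]
    jmin = dst[o_min][first]
    lmax = cue_levels[jmax]
    lmin = cue_levels[jmin]
    delta = lmax - lmin
    pos = pop.xy
    vmax = pos[jmax] - pos[focal]
    vmin = pos[jmin] - pos[focal]

    def _unit(v):
        n = np.linalg.norm(v, axis=1)
        out = np.zeros_like(v)
        ok = n > 0
        out[ok] = v[ok] / n[ok, None]
        return out

    v = params.migration_gain * delta[:, None] * (_unit(vmax) - _unit(vmin))
    if mode == "repel":
        v = -v
    v[delta <= 0] = 0.0
    nrm = np.linalg.norm(v, axis=1)
    over = nrm > params.max_step
    v[over] *= (params.max_step / nrm[over])[:, None]
    lookup = {int(c): k for k, c in enumerate(mel_idx)}
    for row, f in enumerate(focal):
        disp[lookup[int(f)]] = v[row]
    return disp


def _wall_ghost_counts(xy: np.ndarray, radius: float,
                       side: float) -> np.ndarray:
    """Crowding contributed by the dish walls, as mirror-image ghosts.

    The contact-inhibition rule counts neighbours within a radius; a cell
    against the wall has half its neighbourhood amputated and would
    otherwise always look uncrowded and divide without bound.  Reflecting
    the nearby cells (and the cell itself) across each wall restores the
    crowding an impenetrable boundary exerts."""
    from scipy.spatial import cKDTree
    ghosts = []
    for dim in (0, 1):
        for wall in (0.0, side):
            near = np.abs(xy[:, dim] - wall) <= radius
            if near.any():
                g = xy[near].copy()
                g[:, dim] = 2.0 * wall - g[:, dim]
                ghosts.append(g)
    for wx in (0.0, side):
        for wy in (0.0, side):
            near = (np.abs(xy[:, 0] - wx) <= radius) & \
                   (np.abs(xy[:, 1] - wy) <= radius)
            if near.any():
                g = xy[near].copy()
                g[:, 0] = 2.0 * wx - g[:, 0]
                g[:, 1] = 2.0 * wy - g[:, 1]
                ghosts.append(g)
    if not ghosts:
        return np.zeros(len(xy), dtype=np.int64)
    tree = cKDTree(np.vstack(ghosts))
    return np.asarray(tree.query_ball_point(xy, radius, return_length=True),
                      dtype=np.int64)


def step(state: SimulationState, params: SimulationParams,
         mechanism: Mechanism | str) -> SimulationState:
    """Advance the state one iteration through all phases."""
    mech = Mechanism(mechanism)
    pop = state.population.sort_by_id().copy()
    rng = state.rng
    dish = state.dish
    sig, cyc, mpar = params.signal, params.cycle, params.mechanics
    n = len(pop)
    events = {"divisions": 0, "deaths": 0, "stratified": 0}
    if n == 0:
        new = SimulationState(state.iteration + 1, pop, rng, dish)
        new.events = events
        return new

    r = float(pop.radius.max())
    mel_mask = pop.is_mel()
    ker_mask = ~mel_mask

    # ---- signalling: production -> outflux -> influx -> degradation ------
    pairs = neighbor_pairs(pop.xy, sig.diffusion_neighbor_radius)
    prod_R = np.zeros(n)
    prod_A = np.zeros(n)
    if mech.uses_R:
        prod_R[mel_mask] = sig.production_R
    if mech == Mechanism.ATTRACTANT_A_BINARY:
        contact = np.zeros(n, dtype=bool)
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            contact[a[mel_mask[b]]] = True
            contact[b[mel_mask[a]]] = True
        prod_A[ker_mask & ~contact] = sig.production_A_binary
    elif mech == Mechanism.ATTRACTANT_A_CONTINUOUS:
        prod_A[ker_mask] = produce_A_continuous(pop.level_R[ker_mask], sig)
    if mech.uses_R:
        pop.level_R = diffusion_step_levels(
            pop.level_R, pop.xy, prod_R, sig.outflux_fraction,
            sig.degradation_fraction_R, sig.diffusion_neighbor_radius, pairs)
    if mech.uses_A:
        pop.level_A = diffusion_step_levels(
            pop.level_A, pop.xy, prod_A, sig.outflux_fraction,
            sig.degradation_fraction_A, sig.diffusion_neighbor_radius, pairs)

    if not params.signals_only:
        guiding = pop.level_R if mech.cue == "R" else pop.level_A

        # ---- cycle advance (contact inhibition + melanocyte signal gate) --
        if cyc.free_space_radius == sig.diffusion_neighbor_radius:
            space_pairs = pairs
        else:
            space_pairs = neighbor_pairs(pop.xy, cyc.free_space_radius)
        crowd = np.zeros(n, dtype=np.int64)
        if len(space_pairs):
            np.add.at(crowd, space_pairs[:, 0], 1)
            np.add.at(crowd, space_pairs[:, 1], 1)
        crowd += _wall_ghost_counts(pop.xy, cyc.free_space_radius, dish.side)
        # contact inhibition is both a count and a pressure condition: a
        # cell still overlapping its neighbours after relaxation has no
        # free space either, whatever its neighbour count
        depth = np.zeros(n)
        tpairs = neighbor_pairs(pop.xy, 2.0 * r)
        if len(tpairs):
            td = np.linalg.norm(pop.xy[tpairs[:, 1]] - pop.xy[tpairs[:, 0]],
                                axis=1)
            od = 2.0 * r - td
            np.maximum.at(depth, tpairs[:, 0], od)
            np.maximum.at(depth, tpairs[:, 1], od)
        adv = (crowd <= cyc.free_space_max_neighbors) & \
              (depth <= cyc.division_max_overlap)
        if mech.cue == "R":
            sig_ok = guiding < cyc.mel_proliferation_signal_max_R
        else:
            sig_ok = guiding > cyc.mel_proliferation_signal_min_A
        adv &= ~mel_mask | sig_ok
        ta = pop.types == int(CellType.TA_KERATINOCYTE)
        adv &= ~ta | (pop.divisions < cyc.max_ta_divisions)
        pop.cycle[adv] += 1

        # ---- melanocyte death (after a signal-equilibration warm-up) ------
        die = np.zeros(n, dtype=bool)
        if state.iteration >= cyc.death_warmup_iterations:
            if mech.cue == "R":
                die = mel_mask & (guiding >= cyc.mel_death_signal_min_R)
            else:
                die = mel_mask & (guiding <= cyc.mel_death_signal_max_A)
        if die.any():
            events["deaths"] = int(die.sum())
            pop = pop.take(np.flatnonzero(~die))
            mel_mask = pop.is_mel()
            n = len(pop)

        # ---- division (processed in id order; daughters get fresh ids) ----
        thr = np.where(pop.types == int(CellType.MELANOCYTE),
                       cyc.division_threshold_mel,
                       np.where(pop.types == int(CellType.STEM_KERATINOCYTE),
                                cyc.division_threshold_stem,
                                cyc.division_threshold_ta))
        dividers = np.flatnonzero(pop.cycle >= thr)
        if len(dividers):
            next_id = pop.next_id()
            daughters: list[Cell] = []
            for i in dividers:
                mother = Cell(int(pop.ids[i]), CellType(int(pop.types[i])),
                              float(pop.xy[i, 0]), float(pop.xy[i, 1]),
                              float(pop.radius[i]), float(pop.level_R[i]),
                              float(pop.level_A[i]), int(pop.cycle[i]),
                              int(pop.divisions[i]))
                mother, daughter = dynamics.attempt_division(
                    mother, rng, cyc, next_id)
                if daughter is None:
                    continue
                next_id += 1
                daughters.append(daughter)
                pop.level_R[i] = mother.level_R
                pop.level_A[i] = mother.level_A
                pop.cycle[i] = mother.cycle_counter
                pop.divisions[i] = mother.divisions_done
            if daughters:
                events["divisions"] = len(daughters)
                dpop = Population.from_cells(daughters)
                pop = Population(*(np.concatenate(
                    [getattr(pop, s), getattr(dpop, s)])
                    for s in Population.__slots__))
                n = len(pop)
                mel_mask = pop.is_mel()
                ta = pop.types == int(CellType.TA_KERATINOCYTE)

        # ---- migration -----------------------------------------------------
        disp = np.zeros((n, 2))
        ta = pop.types == int(CellType.TA_KERATINOCYTE)
        n_ta = int(ta.sum())
        if n_ta and mpar.ta_random_step > 0:
            phi = rng.uniform(0.0, 2.0 * np.pi, size=n_ta)
            disp[ta] = mpar.ta_random_step * np.column_stack(
                [np.cos(phi), np.sin(phi)])
        mel_idx = np.flatnonzero(mel_mask)
        if len(mel_idx):
            cue = pop.level_R if mech.cue == "R" else pop.level_A
            mig_pairs = neighbor_pairs(pop.xy, sig.diffusion_neighbor_radius)
            disp[mel_idx] = _chemotaxis_bulk(pop, mel_idx, cue, mig_pairs,
                                             mech.migration_mode, mpar)
        pop.xy = pop.xy + mpar.substrate_damping * disp

        # ---- contact mechanics ---------------------------------------------
        pop.xy = resolve_overlaps(pop.xy, r, mpar, rng, dish)
        pop.xy = apply_adhesion(pop.xy, r, mpar)
        pop.xy = clamp_to_dish(pop.xy, dish, r)

        # ---- stratification removal ----------------------------------------
        crowd2 = np.zeros(n, dtype=np.int64)
        cpairs = neighbor_pairs(pop.xy, cyc.free_space_radius)
        if len(cpairs):
            np.add.at(crowd2, cpairs[:, 0], 1)
            np.add.at(crowd2, cpairs[:, 1], 1)
        crowd2 += _wall_ghost_counts(pop.xy, cyc.free_space_radius, dish.side)
        strat = dynamics.stratification_mask(pop.types, pop.divisions,
                                             crowd2, cyc)
        if strat.any():
            events["stratified"] = int(strat.sum())
            pop = pop.take(np.flatnonzero(~strat))

    if np.isnan(pop.xy).any() or np.isnan(pop.level_R).any() \
            or np.isnan(pop.level_A).any():
        bad = np.flatnonzero(np.isnan(pop.xy).any(axis=1)
                             | np.isnan(pop.level_R)
                             | np.isnan(pop.level_A))
        raise RuntimeError(
            f"NaN at iteration {state.iteration + 1}, cell ids "
            f"{pop.ids[bad][:5].tolist()}")

    new = SimulationState(state.iteration + 1, pop, rng, dish)
    new.events = events
    return new


def run(params: SimulationParams, mechanism: Mechanism | str,
        scenario: Scenario, n_iterations: int, seed: int,
        record_metrics: bool = True
        ) -> tuple[SimulationState, list[metrics.MetricsRecord]]:
    """Initialise and advance ``n_iterations`` iterations, recording the
    evenness metrics each iteration.  480 iterations cover the 10-day
    reference experiment.  Fully reproducible per (params, scenario, seed).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    state = init_state(params, scenario, seed)
    min_excl = 2 if params.neighbor_count_inclusive else 3
    series: list[metrics.MetricsRecord] = []
    for _ in range(n_iterations):
        state = step(state, params, mechanism)
        if record_metrics:
            series.append(metrics.collect_record(
                state, min_neighbors_exclusive=min_excl))
    return state, series
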