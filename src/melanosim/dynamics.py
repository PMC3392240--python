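"""Cell-cycle progression, division, differentiation, melanocyte death and
stratification removal.

Keratinocyte rules: stem keratinocytes are immortal and divide under
contact inhibition; at each stem division the daughter commits to the
transit-amplifying (TA) fate with a fixed probability (asymmetric
division).  TA keratinocytes divide a bounded number of times and then
leave the basal layer (stratify) once crowding squeezes them out; since
the model is a strict monolayer, stratification is deletion.

Melanocyte rules: cycle progression additionally requires the guidance
signal to indicate melanocyte scarcity (low repellent R, or high
attractant A, depending on the active mechanism); a signal indicating
severe melanocyte excess kills the cell.  These thresholds are the knobs
calibrated to establish target melanocyte densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Cell, CellType


@dataclass(frozen=True)
class CycleParams:
    """Cell-cycle, differentiation and removal parameters.

    Thresholds are in iterations (30 min each); the keratinocyte defaults
    give a ~24 h cycle at zero crowding.  ``free_space_*`` implement
    contact inhibition: the counter only advances when at most
    ``free_space_max_neighbors`` cells sit within ``free_space_radius`` µm.
    The ``mel_*`` signal bands gate melanocyte proliferation and death; the
    death band always indicates strictly more melanocyte crowding than the
    proliferation band allows.
    """

    division_threshold_stem: int = 48
    division_threshold_ta: int = 48
    division_threshold_mel: int = 72
    max_ta_divisions: int = 3
    free_space_radius: float = 25.0
    free_space_max_neighbors: int = 5
    stem_to_ta_probability: float = 0.5
    # mechanism R: proliferate while R below max; die at/above death min
    mel_proliferation_signal_max_R: float = 1.0
    mel_death_signal_min_R: float = 3.0
    # mechanisms A-bin / A-cont: proliferate while A above min; die at/below max
    mel_proliferation_signal_min_A: float = 1.0
    mel_death_signal_max_A: float = 0.3
    crowding_removal_neighbors: int = 4  # exhausted TA detaches above this
    division_max_overlap: float = 1.0  # µm; compressed cells do not cycle
    death_warmup_iterations: int = 48

    def __post_init__(self) -> None:
        for name in ("division_threshold_stem", "division_threshold_ta",
                     "division_threshold_mel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.stem_to_ta_probability <= 1.0):
            raise ValueError("stem_to_ta_probability must be in [0, 1]")
        if self.max_ta_divisions < 0:
            raise ValueError("max_ta_divisions must be >= 0")
        if self.mel_death_signal_min_R <= self.mel_proliferation_signal_max_R:
            raise ValueError("R death band must exceed proliferation band")
        if self.mel_death_signal_max_A >= self.mel_proliferation_signal_min_A:
            raise ValueError("A death band must lie below proliferation band")


VALID_MECHANISMS = ("R", "A-bin", "A-cont")


def _check_mechanism(mechanism: str) -> None:
    if mechanism not in VALID_MECHANISMS:
        raise ValueError(
            f"unknown mechanism {mechanism!r}; expected one of {VALID_MECHANISMS}")


def mel_proliferation_allowed(guiding_signal: float, params: CycleParams,
                              mechanism: str) -> bool:
    """Whether the guidance signal permits melanocyte cycle progression.

    Under mechanism R the melanocyte's own repellent level reports local
    melanocyte crowding, so progression requires it below a ceiling; under
    the attractant mechanisms a high attractant level marks underserved
    keratinocytes, so progression requires it above a floor.
    """
    _check_mechanism(mechanism)
    if mechanism == "R":
        return guiding_signal < params.mel_proliferation_signal_max_R
    return guiding_signal > params.mel_proliferation_signal_min_A


def advance_cycle(cell: Cell, local_crowding: int, guiding_signal: float,
                  params: CycleParams, mechanism: str) -> Cell:
    """Return a copy of ``cell`` with the cycle counter advanced when the
    progression conditions hold.

    All types require free space (contact inhibition).  Melanocytes
    additionally require the signal condition of the active mechanism.
    TA keratinocytes that have exhausted their division budget no longer
    progress.  Keratinocyte progression never reads R or A.
    """
    _check_mechanism(mechanism)
    ok = local_crowding <= params.free_space_max_neighbors
    if cell.type == CellType.MELANOCYTE:
        ok = ok and mel_proliferation_allowed(guiding_signal, params, mechanism)
    elif cell.type == CellType.TA_KERATINOCYTE:
        ok = ok and cell.divisions_done < params.max_ta_divisions
    if not ok:
        return cell
    return Cell(cell.id, cell.type, cell.x, cell.y, cell.radius,
                cell.level_R, cell.level_A, cell.cycle_counter + 1,
                cell.divisions_done)


def division_threshold(cell_type: CellType, params: CycleParams) -> int:
    return {CellType.STEM_KERATINOCYTE: params.division_threshold_stem,
            CellType.TA_KERATINOCYTE: params.division_threshold_ta,
            CellType.MELANOCYTE: params.division_threshold_mel}[cell_type]


def attempt_division(cell: Cell, rng: np.random.Generator,
                     params: CycleParams,
                     daughter_id: int) -> tuple[Cell, Optional[Cell]]:
    """Divide ``cell`` if its counter has reached the type's threshold.

    Returns (updated mother, daughter or None).  The daughter is placed one
    radius from the mother at a uniformly random angle (overlap is resolved
    later by the mechanics phase).  Stem mothers produce a TA daughter with
    probability ``stem_to_ta_probability``, else a stem daughter.  TA
    mothers and daughters both advance their division count.  Melanocyte
    divisions split both substance compartments in half, conserving totals.
    """
    if cell.cycle_counter < division_threshold(cell.type, params):
        return cell, None
    phi = rng.uniform(0.0, 2.0 * np.pi)
    dx = cell.radius * np.cos(phi)
    dy = cell.radius * np.sin(phi)
    if cell.type == CellType.STEM_KERATINOCYTE:
        dtype = (CellType.TA_KERATINOCYTE
                 if rng.uniform() < params.stem_to_ta_probability
                 else CellType.STEM_KERATINOCYTE)
        mother = Cell(cell.id, cell.type, cell.x, cell.y, cell.radius,
                      cell.level_R, cell.level_A, 0, cell.divisions_done)
        daughter = Cell(daughter_id, dtype, cell.x + dx, cell.y + dy,
                        cell.radius, 0.0, 0.0, 0, 0)
    elif cell.type == CellType.TA_KERATINOCYTE:
        mother = Cell(cell.id, cell.type, cell.x, cell.y, cell.radius,
                      cell.level_R, cell.level_A, 0, cell.divisions_done + 1)
        daughter = Cell(daughter_id, CellType.TA_KERATINOCYTE,
                        cell.x + dx, cell.y + dy, cell.radius,
                        0.0, 0.0, 0, cell.divisions_done + 1)
    else:  # melanocyte: substance split in half, total conserved
        half_R, half_A = 0.5 * cell.level_R, 0.5 * cell.level_A
        mother = Cell(cell.id, cell.type, cell.x, cell.y, cell.radius,
                      half_R, half_A, 0, cell.divisions_done)
        daughter = Cell(daughter_id, CellType.MELANOCYTE,
                        cell.x + dx, cell.y + dy, cell.radius,
                        half_R, half_A, 0, 0)
    return mother, daughter


def melanocyte_death_check(cell: Cell, guiding_signal: float,
                           params: CycleParams, mechanism: str) -> bool:
    """True when the signal indicates severe melanocyte excess and the cell
    should be removed: R at/above ``mel_death_signal_min_R`` under
    mechanism R, or A at/below ``mel_death_signal_max_A`` under the
    attractant mechanisms."""
    _check_mechanism(mechanism)
    if cell.type != CellType.MELANOCYTE:
        raise ValueError("death check applies to melanocytes only")
    if mechanism == "R":
        return guiding_signal >= params.mel_death_signal_min_R
    return guiding_signal <= params.mel_death_signal_max_A


def stratification_mask(types: np.ndarray, divisions: np.ndarray,
                        local_crowding: np.ndarray,
                        params: CycleParams) -> np.ndarray:
    """Boolean mask of TA keratinocytes leaving the basal layer.

    A TA cell detaches when (a) its division budget is exhausted and
    (b) it is crowded — more than ``crowding_removal_neighbors`` cells in
    its contact-inhibition neighbourhood, so there is no space left for it
    on the membrane.  This is the pressure valve of the monolayer: it
    converts the division influx at confluence into an upward (deleted)
    outflux.  Stem keratinocytes and melanocytes are never removed by this
    rule; an exhausted TA with free space stays put.
    """
    exhausted = (types == int(CellType.TA_KERATINOCYTE)) & \
                (divisions >= params.max_ta_divisions)
    return exhausted & (local_crowding > params.crowding_removal_neighbors)
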