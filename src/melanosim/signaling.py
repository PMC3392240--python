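"""Production, cell-to-cell diffusion and degradation of substances R and A.

Signals live in per-cell compartments: each cell holds an amount of the
melanocyte-produced repellent R and of the keratinocyte-produced attractant
A.  Diffusion is modelled as exchange between neighbouring compartments —
each iteration a cell emits a constant fraction of its current amount,
shared equally among its neighbours — followed by first-order degradation.
This compartment picture stands in for gap-junction transport of small
signalling molecules; the cells themselves are the compartments, so
proliferation, stratification and migration automatically redistribute
substance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cell, CellType, neighbor_pairs


@dataclass(frozen=True)
class SignalParams:
    """Rates and geometry of the signalling model.

    Amounts are dimensionless per-cell quantities (cells are uniform
    spheres, so no volume normalisation is applied); rates are per
    30-minute iteration.

    production_R
        Constant R production in every melanocyte.
    production_A_binary
        Constant A production in keratinocytes lacking melanocyte contact
        (binary regime).
    G_max, theta, hill_n
        Continuous-regime A production G_max / (1 + (R/θ)^n): maximal rate,
        R level at half-maximal production, and the Hill exponent.
    outflux_fraction
        Fraction of a cell's current amount emitted to its neighbours each
        iteration, shared equally among them.
    degradation_fraction_R / degradation_fraction_A
        First-order decay fractions applied after flux exchange.
    diffusion_neighbor_radius
        Center-to-center distance (µm) defining the compartment adjacency;
        also the "immediate neighbourhood" used for the binary regime's
        melanocyte-contact test.
    """

    production_R: float = 1.0
    production_A_binary: float = 1.0
    G_max: float = 1.0
    theta: float = 3.0
    hill_n: float = 2.0
    outflux_fraction: float = 0.4
    degradation_fraction_R: float = 0.06
    degradation_fraction_A: float = 0.02
    diffusion_neighbor_radius: float = 25.0

    def __post_init__(self) -> None:
        for name in ("production_R", "production_A_binary", "G_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("outflux_fraction", "degradation_fraction_R",
                     "degradation_fraction_A"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.diffusion_neighbor_radius <= 0:
            raise ValueError("diffusion_neighbor_radius must be > 0")


# ---------------------------------------------------------------------------
# production
# ---------------------------------------------------------------------------

def produce_R(cell: Cell, params: SignalParams) -> float:
    """R production this iteration: a constant rate in melanocytes, zero in
    both keratinocyte types."""
    if cell.type == CellType.MELANOCYTE:
        return params.production_R
    return 0.0


def produce_A_binary(cell: Cell, has_melanocyte_contact: bool,
                     params: SignalParams) -> float:
    """Binary-regime A production: a constant rate in keratinocytes without
    a melanocyte in their immediate neighbourhood, zero otherwise.

    Melanocytes never produce A.
    """
    if cell.type == CellType.MELANOCYTE:
        return 0.0
    return 0.0 if has_melanocyte_contact else params.production_A_binary


def produce_A_continuous(level_R: float | np.ndarray,
                         params: SignalParams) -> float | np.ndarray:
    """Continuous-regime A production: repressive Hill response to R.

    Returns G_max / (1 + (R/θ)^n).  R here acts purely as a proxy for the
    distance to surrounding melanocytes, not as a repellent: production is
    maximal far from any melanocyte (R → 0) and half-maximal at R = θ.
    """
    level_R = np.asarray(level_R, dtype=float)
    if np.any(level_R < 0):
        raise ValueError("level_R must be >= 0")
    out = params.G_max / (1.0 + (level_R / params.theta) ** params.hill_n)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# diffusion / degradation
# ---------------------------------------------------------------------------

def degradation_amount(level: float, fraction: float) -> float:
    """Amount removed by first-order decay: fraction × level."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("degradation fraction must be in [0, 1)")
    return fraction * level


def diffusion_step_levels(levels: np.ndarray, xy: np.ndarray,
                          production: np.ndarray,
                          outflux_fraction: float,
                          degradation_fraction: float,
                          neighbor_radius: float,
                          pairs: np.ndarray | None = None) -> np.ndarray:
    """One synchronous compartment-exchange update for one substance.

    Phase order within the update: (1) add production, (2) emit outflux =
    outflux_fraction × current amount, split equally among neighbours
    (isolated cells emit nothing, so substance never leaves a one-cell
    component), (3) add the influx addressed to each cell, (4) apply
    first-order degradation to the post-flux level.

    With production and degradation zero the update is conservative: the
    emitted shares are exactly the amounts received.
    """
    if not (0.0 <= outflux_fraction < 1.0):
        raise ValueError("outflux_fraction must be in [0, 1)")
    if not (0.0 <= degradation_fraction < 1.0):
        raise ValueError("degradation_fraction must be in [0, 1)")
    levels = np.asarray(levels, dtype=float) + np.asarray(production, dtype=float)
    n = len(levels)
    if pairs is None:
        pairs = neighbor_pairs(np.asarray(xy, dtype=float), neighbor_radius)
    degree = np.zeros(n, dtype=np.int64)
    if len(pairs):
        np.add.at(degree, pairs[:, 0], 1)
        np.add.at(degree, pairs[:, 1], 1)
    # share emitted to EACH neighbour; outflux only where degree > 0
    share = np.zeros(n)
    has_nb = degree > 0
    share[has_nb] = outflux_fraction * levels[has_nb] / degree[has_nb]
    influx = np.zeros(n)
    if len(pairs):
        np.add.at(influx, pairs[:, 1], share[pairs[:, 0]])
        np.add.at(influx, pairs[:, 0], share[pairs[:, 1]])
    post = levels - share * degree + influx
    post *= (1.0 - degradation_fraction)
    return post


def diffusion_step(cells, substance: str, params: SignalParams,
                   production: np.ndarray | None = None) -> np.ndarray:
    """Convenience wrapper over :func:`diffusion_step_levels` for a list of
    :class:`Cell` records; returns the updated level array (cell order
    preserved), without mutating the inputs.

    ``substance`` is ``"R"`` or ``"A"``; ``production`` defaults to zero
    (pure transport + decay).
    """
    cells = list(cells)
    if substance not in ("R", "A"):
        raise ValueError("substance must be 'R' or 'A'")
    xy = np.array([[c.x, c.y] for c in cells]).reshape(-1, 2)
    levels = np.array([c.level_R if substance == "R" else c.level_A
                       for c in cells])
    if production is None:
        production = np.zeros(len(cells))
    frac = (params.degradation_fraction_R if substance == "R"
            else params.degradation_fraction_A)
    return diffusion_step_levels(levels, xy, production,
                                 params.outflux_fraction, frac,
                                 params.diffusion_neighbor_radius)


def transition_matrix(xy: np.ndarray, outflux_fraction: float,
                      degradation_fraction: float,
                      neighbor_radius: float) -> np.ndarray:
    """Dense one-step transfer matrix M such that new = (1-d)·(M @ (old+P)).

    Built explicitly from the pairwise adjacency; intended as an independent
    cross-check of :func:`diffusion_step_levels` on small populations, and
    for steady-state analysis.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    adj = (d <= neighbor_radius) & ~np.eye(n, dtype=bool)
    degree = adj.sum(axis=1)
    M = np.zeros((n, n))
    for j in range(n):
        if degree[j] > 0:
            M[adj[:, j], j] = outflux_fraction / degree[j]
            M[j, j] = 1.0 - outflux_fraction
        else:
            M[j, j] = 1.0
    return (1.0 - degradation_fraction) * M
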