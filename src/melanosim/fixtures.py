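"""Deterministic synthetic cell configurations.

These generators produce hand-checkable layouts used both by the scenario
initialiser (rim-restricted gradient visualisation) and as oracles in
tests: hexagonal packings with a prescribed melanocyte fraction, complete
spatial randomness (CSR) placements, single-ring rim layouts, and exact
square lattices of melanocytes (whose nearest-neighbour distances have
zero spread by construction).
"""

from __future__ import annotations

import numpy as np

from .core import Cell, CellType, Dish, DEFAULT_CELL_RADIUS


def hex_packing_positions(side: float, spacing: float, margin: float,
                          with_indices: bool = False):
    """Centres of a hexagonal packing filling [margin, side-margin]²
    with nearest-neighbour distance ``spacing``.  With ``with_indices``
    also returns the (row, col) lattice indices of each centre."""
    row_h = spacing * np.sqrt(3.0) / 2.0
    xs, ys, rows, cols = [], [], [], []
    y = margin
    row = 0
    while y <= side - margin:
        x0 = margin + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        col = 0
        while x <= side - margin:
            xs.append(x)
            ys.append(y)
            rows.append(row)
            cols.append(col)
            x += spacing
            col += 1
        y += row_h
        row += 1
    xy = np.column_stack([xs, ys])
    if with_indices:
        return xy, np.array(rows), np.array(cols)
    return xy


def hex_packing(melanocyte_fraction: float, dish: Dish | None = None,
                spacing: float = 2.0 * DEFAULT_CELL_RADIUS,
                seed: int = 0, arrangement: str = "random") -> list[Cell]:
    """Hexagonally packed dish with melanocytes at the given fraction;
    remaining cells are TA keratinocytes.

    ``arrangement="random"`` assigns each site independently.
    ``arrangement="uniform"`` places melanocytes on a regular sublattice
    (every a-th column of every a-th row with a·a ≈ 1/fraction); at
    fraction 1/4 this gives every keratinocyte a melanocyte within one
    lattice spacing — the saturation regime in which binary attractant
    production shuts down globally.
    """
    dish = dish or Dish()
    xy, rows, cols = hex_packing_positions(dish.side, spacing,
                                           DEFAULT_CELL_RADIUS,
                                           with_indices=True)
    if arrangement == "random":
        rng = np.random.default_rng(seed)
        is_mel = rng.uniform(size=len(xy)) < melanocyte_fraction
    elif arrangement == "uniform":
        if melanocyte_fraction <= 0:
            is_mel = np.zeros(len(xy), dtype=bool)
        else:
            a = int(round(np.sqrt(1.0 / melanocyte_fraction)))
            if a < 1 or abs(a * a * melanocyte_fraction - 1.0) > 0.05:
                raise ValueError(
                    "uniform arrangement needs a fraction close to 1/a² "
                    f"for integer a; got {melanocyte_fraction}")
            is_mel = (rows % a == 0) & (cols % a == 0)
    else:
        raise ValueError("arrangement must be 'random' or 'uniform'")
    return [
        Cell(i, CellType.MELANOCYTE if m else CellType.TA_KERATINOCYTE,
             float(x), float(y))
        for i, ((x, y), m) in enumerate(zip(xy, is_mel))
    ]


def csr(n_melanocytes: int, dish: Dish | None = None, seed: int = 0,
        n_keratinocytes: int = 0) -> list[Cell]:
    """Complete-spatial-randomness placement: points uniform over the full
    dish, melanocytes first, then keratinocytes.  The null baseline for
    the evenness statistics."""
    dish = dish or Dish()
    rng = np.random.default_rng(seed)
    n = n_melanocytes + n_keratinocytes
    xy = rng.uniform(DEFAULT_CELL_RADIUS, dish.side - DEFAULT_CELL_RADIUS,
                     size=(n, 2))
    cells = []
    for i in range(n):
        t = CellType.MELANOCYTE if i < n_melanocytes else CellType.TA_KERATINOCYTE
        cells.append(Cell(i, t, float(xy[i, 0]), float(xy[i, 1])))
    return cells


def rim_layout(dish: Dish | None = None,
               spacing: float = 2.0 * DEFAULT_CELL_RADIUS,
               keratinocyte_spacing: float | None = None) -> list[Cell]:
    """Melanocytes in a single-cell ring against the dish wall with TA
    keratinocytes hex-packed over the interior (global-gradient
    visualisation scenario)."""
    dish = dish or Dish()
    r = DEFAULT_CELL_RADIUS
    lo, hi = r, dish.side - r
    ring = []
    t = np.arange(lo, hi, spacing)
    for x in t:
        ring.append((x, lo))
        ring.append((x, hi))
    for y in t[1:]:
        ring.append((lo, y))
        ring.append((hi, y))
    ks = keratinocyte_spacing or spacing
    interior = hex_packing_positions(dish.side, ks, r + spacing)
    cells = [Cell(i, CellType.MELANOCYTE, float(x), float(y))
             for i, (x, y) in enumerate(ring)]
    n0 = len(cells)
    cells += [Cell(n0 + i, CellType.TA_KERATINOCYTE, float(x), float(y))
              for i, (x, y) in enumerate(interior)]
    return cells


def lattice_melanocytes(n_per_side: int = 5, spacing: float = 40.0,
                        dish: Dish | None = None) -> list[Cell]:
    """Exact square lattice of melanocytes centred in the dish: every
    nearest-neighbour distance equals ``spacing``, so the spread of
    nearest-neighbour distances is exactly zero."""
    dish = dish or Dish()
    extent = (n_per_side - 1) * spacing
    if extent > dish.side - 2 * DEFAULT_CELL_RADIUS:
        raise ValueError("lattice does not fit in the dish")
    off = (dish.side - extent) / 2.0
    cells = []
    i = 0
    for a in range(n_per_side):
        for b in range(n_per_side):
            cells.append(Cell(i, CellType.MELANOCYTE,
                              off + a * spacing, off + b * spacing))
            i += 1
    return cells


FIXTURE_KINDS = ("hex_packing", "csr", "rim", "lattice_melanocytes")


def generate_fixture(kind: str, **kwargs) -> list[Cell]:
    """Dispatch by fixture kind name (CLI entry point)."""
    if kind == "hex_packing":
        return hex_packing(**kwargs)
    if kind == "csr":
        return csr(**kwargs)
    if kind == "rim":
        return rim_layout(**kwargs)
    if kind == "lattice_melanocytes":
        return lattice_melanocytes(**kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}; expected {FIXTURE_KINDS}")
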