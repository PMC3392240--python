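"""Persistence: state snapshots, metrics tables and run manifests.

Snapshots are line-delimited JSON records (one cell per line: id, type,
x, y, level_R, level_A, cycle_counter, divisions_done) — no bioimaging
standard fits an abstract cell-centre state, and NDJSON diffs and streams
well.  Metrics series and replicate summaries are tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import Cell, CellType, Dish, SimulationState, Population
from .metrics import MetricsRecord, ReplicateSummary

SNAPSHOT_FIELDS = ("id", "type", "x", "y", "level_R", "level_A",
                   "cycle_counter", "divisions_done")


def save_snapshot(state: SimulationState, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {"iteration": state.iteration, "dish_side": state.dish.side,
                  "observation_margin": state.dish.observation_margin}
        fh.write(json.dumps({"_header": header}) + "\n")
        for c in state.cells:
            rec = {"id": c.id, "type": c.type.name, "x": c.x, "y": c.y,
                   "level_R": c.level_R, "level_A": c.level_A,
                   "cycle_counter": c.cycle_counter,
                   "divisions_done": c.divisions_done}
            fh.write(json.dumps(rec) + "\n")


def load_snapshot(path: str | Path, seed: int | None = 0) -> SimulationState:
    path = Path(path)
    cells: list[Cell] = []
    header = {}
    with path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            if "_header" in rec:
                header = rec["_header"]
                continue
            cells.append(Cell(
                id=rec["id"], type=CellType[rec["type"]],
                x=rec["x"], y=rec["y"],
                level_R=rec["level_R"], level_A=rec["level_A"],
                cycle_counter=rec["cycle_counter"],
                divisions_done=rec["divisions_done"]))
    dish = Dish(side=header.get("dish_side", 400.0),
                observation_margin=header.get("observation_margin", 50.0))
    return SimulationState.from_cells(cells, seed=seed, dish=dish,
                                      iteration=header.get("iteration", 0))


def metrics_to_frame(series: Sequence[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "iteration": r.iteration,
        "n_cells_obs": r.n_cells_obs,
        "melanocyte_count_obs": r.melanocyte_count_obs,
        "melanocyte_density": r.melanocyte_density,
        "n_many_neighbors": r.n_with_many_neighbors,
        "neighbor_ratio": r.neighbor_ratio,
        "mdist": r.mdist,
        "sddist": r.sddist,
    } for r in series])


def summaries_to_frame(summaries: Sequence[ReplicateSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mechanism": s.mechanism,
        "target_density": s.target_density,
        "seed": s.seed,
        "neighbor_ratio": s.neighbor_ratio,
        "relsd": s.relsd,
        "melanocyte_density": s.melanocyte_density,
    } for s in summaries])


def save_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True)
                          + "\n")


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
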