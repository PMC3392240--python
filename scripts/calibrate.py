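"""Calibrate the density-control parameters of the melanocyte model.

Two stages:

1. Reference thresholds (one pair per mechanism, cell-intrinsic, shared
   by all experiments): hexagonally pack the dish at the 10% reference
   melanocyte fraction with unit production, freeze all cell dynamics,
   run the signalling to steady state and record the mean guidance level
   at melanocytes.  That level becomes the proliferation ceiling
   (repellent) or floor (attractants); the death band sits DEATH_RATIO
   beyond it.
2. Production scale per (mechanism, target density): bisect a multiplier
   on the mechanism's production rate until full live runs (two seeds,
   480 iterations, near-confluent random seeding) end at the target
   density.  Density falls with production under the repellent (levels
   reach the fixed ceiling earlier) and rises with production under the
   attractants (levels clear the fixed floor more easily).

Writes both tables into src/melanosim/presets.py between the markers.

Usage:  python scripts/calibrate.py [--quick]
"""

from __future__ import annotations

import argparse
import re
import sys
from dataclasses import replace
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from melanosim import engine, metrics  # noqa: E402
from melanosim.core import SimulationState  # noqa: E402
from melanosim.dynamics import CycleParams  # noqa: E402
from melanosim.engine import Scenario, SimulationParams, Mechanism  # noqa: E402
from melanosim.fixtures import hex_packing  # noqa: E402
from melanosim.presets import DEATH_RATIO, TARGET_DENSITIES  # noqa: E402
from melanosim.signaling import SignalParams  # noqa: E402

PRESETS_PATH = Path(__file__).resolve().parents[1] / "src" / "melanosim" / "presets.py"
REFERENCE_DENSITY = 0.10


def frozen_level(mech: Mechanism, density: float, n_seeds: int = 3,
                 n_iter: int = 250) -> float:
    params = SimulationParams(signals_only=True)
    vals = []
    for seed in range(n_seeds):
        cells = hex_packing(density, seed=seed)
        st = SimulationState.from_cells(cells, seed=seed)
        for _ in range(n_iter):
            st = engine.step(st, params, mech)
        pop = st.population
        cue = pop.level_R if mech.cue == "R" else pop.level_A
        vals.append(float(cue[pop.is_mel()].mean()))
    return float(np.mean(vals))


def cycle_for(mech: Mechanism, threshold: float) -> CycleParams:
    if mech.cue == "R":
        return CycleParams(mel_proliferation_signal_max_R=threshold,
                           mel_death_signal_min_R=DEATH_RATIO * threshold)
    return CycleParams(mel_proliferation_signal_min_A=threshold,
                       mel_death_signal_max_A=threshold / DEATH_RATIO)


def signal_for(mech: Mechanism, scale: float) -> SignalParams:
    base = SignalParams()
    if mech == Mechanism.REPELLENT_R:
        return replace(base, production_R=scale)
    if mech == Mechanism.ATTRACTANT_A_BINARY:
        return replace(base, production_A_binary=scale)
    return replace(base, G_max=scale)


def endpoint_density(mech: Mechanism, density: float, threshold: float,
                     scale: float, seeds=(101, 102), n_iter: int = 480,
                     n_cells: int = 380) -> float:
    params = SimulationParams(cycle=cycle_for(mech, threshold),
                              signal=signal_for(mech, scale))
    scen = Scenario(initial_cell_count=n_cells,
                    initial_melanocyte_fraction=density)
    out = []
    for seed in seeds:
        _, series = engine.run(params, mech, scen, n_iter, seed)
        out.append(metrics.window_summary(series).melanocyte_density)
    return float(np.mean(out))


def calibrate_scale(mech: Mechanism, density: float, threshold: float,
                    level_at_density: float, n_bisect: int = 8,
                    quick: bool = False) -> float:
    # amplitude-normalisation first guess: scale production so the frozen
    # level at this density matches the fixed threshold
    guess = threshold / level_at_density
    lo, hi = guess / 2.5, guess * 2.5
    n_iter = 240 if quick else 480
    seeds = (101,) if quick else (101, 102)
    # density decreasing in the scale for the repellent, increasing for
    # the attractants
    increasing = mech.cue == "A"
    for _ in range(n_bisect):
        mid = float(np.sqrt(lo * hi))  # bisect in log space
        d = endpoint_density(mech, density, threshold, mid, seeds=seeds,
                             n_iter=n_iter)
        if (d < density) == increasing:
            lo = mid
        else:
            hi = mid
        print(f"  scale={mid:.4f} -> density {d:.3f} (target {density})",
              flush=True)
    s = float(np.sqrt(lo * hi))
    print(f"{mech.value} @ {density}: scale {s:.4f} "
          f"(first guess {guess:.4f})", flush=True)
    return s


def write_presets(thresholds: dict[str, float],
                  scales: dict[tuple[str, float], float]) -> None:
    tbody = "\n".join(f"    {mech!r}: {lvl:.4f},"
                      for mech, lvl in sorted(thresholds.items()))
    sbody = "\n".join(f"    ({mech!r}, {dens}): {s:.4f},"
                      for (mech, dens), s in sorted(scales.items()))
    text = PRESETS_PATH.read_text()
    text = re.sub(r"(# BEGIN THRESHOLD TABLE\n).*?(    # END THRESHOLD TABLE)",
                  r"\1" + tbody + "\n" + r"\2", text, flags=re.S)
    text = re.sub(r"(# BEGIN SCALE TABLE\n).*?(    # END SCALE TABLE)",
                  r"\1" + sbody + "\n" + r"\2", text, flags=re.S)
    PRESETS_PATH.write_text(text)
    print(f"wrote {len(thresholds)} thresholds and {len(scales)} scales "
          f"to {PRESETS_PATH}")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true",
                    help="fewer seeds/iterations (rough pass)")
    ap.add_argument("--densities", type=float, nargs="*",
                    default=list(TARGET_DENSITIES))
    args = ap.parse_args()
    n_seeds = 2 if args.quick else 3
    n_iter = 150 if args.quick else 250
    thresholds: dict[str, float] = {}
    scales: dict[tuple[str, float], float] = {}
    for mech in Mechanism:
        thresholds[mech.value] = frozen_level(mech, REFERENCE_DENSITY,
                                              n_seeds=n_seeds,
                                              n_iter=n_iter)
        print(f"{mech.value}: reference threshold "
              f"{thresholds[mech.value]:.4f}", flush=True)
        for dens in args.densities:
            lev = (thresholds[mech.value] if dens == REFERENCE_DENSITY
                   else frozen_level(mech, dens, n_seeds=n_seeds,
                                     n_iter=n_iter))
            scales[(mech.value, round(dens, 4))] = calibrate_scale(
                mech, dens, thresholds[mech.value], lev, quick=args.quick)
    write_presets(thresholds, scales)


if __name__ == "__main__":
    main()
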