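"""Calibrated run setups per mechanism and target melanocyte density.

The melanocyte proliferation/death thresholds are cell-intrinsic: one
pair per mechanism, fixed across all experiments, anchored to the
steady-state guidance level at the 10% reference density (death requires
a signal ``DEATH_RATIO`` beyond the proliferation band, i.e. strictly
more melanocyte crowding).  What changes between target densities is the
signalling environment: a production-rate scale chosen so that the
guidance level crosses the fixed threshold exactly at the target density.
The guidance level at melanocytes rises with melanocyte density under the
repellent and falls under the attractants, so the production scale falls
with target density for the repellent and rises for the attractants.

Both tables below were produced by ``scripts/calibrate.py``: stage 1
measures frozen-dynamics steady-state levels on hexagonal packings;
stage 2 bisects the production scale against full live runs.

Regenerate with:  python scripts/calibrate.py
"""

from __future__ import annotations

from dataclasses import replace

from .dynamics import CycleParams
from .engine import Mechanism, Scenario, SimulationParams

DEATH_RATIO = 2.5  # death band sits this factor beyond the proliferation band

TARGET_DENSITIES = (0.05, 0.10, 0.25, 0.40)

# fixed per-mechanism proliferation thresholds (guidance level at the 10%
# reference density, frozen dynamics, unit production)
REFERENCE_THRESHOLDS: dict[str, float] = {
    # BEGIN THRESHOLD TABLE
    'A-bin': 18.0740,
    'A-cont': 31.3399,
    'R': 3.3543,
    # END THRESHOLD TABLE
}

# production-rate scale per (mechanism, target density)
PRODUCTION_SCALE: dict[tuple[str, float], float] = {
    # BEGIN SCALE TABLE
    ('A-bin', 0.05): 0.7560,
    ('A-bin', 0.1): 1.1917,
    ('A-bin', 0.25): 7.6121,
    ('A-bin', 0.4): 31.7385,
    ('A-cont', 0.05): 0.9867,
    ('A-cont', 0.1): 1.2351,
    ('A-cont', 0.25): 3.4425,
    ('A-cont', 0.4): 7.6401,
    ('R', 0.05): 1.7043,
    ('R', 0.1): 1.4252,
    ('R', 0.25): 1.0550,
    ('R', 0.4): 0.6942,
    # END SCALE TABLE
}


def calibrated_cycle_params(mechanism: Mechanism | str,
                            base: CycleParams | None = None) -> CycleParams:
    """CycleParams with the mechanism's fixed signal bands."""
    mech = Mechanism(mechanism)
    base = base or CycleParams()
    if mech.value not in REFERENCE_THRESHOLDS:
        raise KeyError(f"no calibrated threshold for mechanism {mech.value!r}")
    level = REFERENCE_THRESHOLDS[mech.value]
    if mech.cue == "R":
        return replace(base,
                       mel_proliferation_signal_max_R=level,
                       mel_death_signal_min_R=DEATH_RATIO * level)
    return replace(base,
                   mel_proliferation_signal_min_A=level,
                   mel_death_signal_max_A=level / DEATH_RATIO)


def scaled_signal_params(mechanism: Mechanism | str, target_density: float,
                         base):
    """SignalParams with the mechanism's production scaled for the target
    density (repellent: production_R; binary attractant:
    production_A_binary; continuous attractant: G_max)."""
    mech = Mechanism(mechanism)
    key = (mech.value, round(float(target_density), 4))
    if key not in PRODUCTION_SCALE:
        raise KeyError(
            f"no calibrated production scale for {key}; available: "
            f"{sorted(PRODUCTION_SCALE)}")
    p = PRODUCTION_SCALE[key]
    if mech == Mechanism.REPELLENT_R:
        return replace(base, production_R=p * base.production_R)
    if mech == Mechanism.ATTRACTANT_A_BINARY:
        return replace(base,
                       production_A_binary=p * base.production_A_binary)
    return replace(base, G_max=p * base.G_max)


def calibrated_setup(mechanism: Mechanism | str, target_density: float,
                     base: SimulationParams | None = None,
                     initial_cell_count: int = 380
                     ) -> tuple[SimulationParams, Scenario]:
    """(params, scenario) for a standard run at a target density: random
    near-confluent seeding at the target melanocyte fraction, fixed
    per-mechanism signal bands, density-calibrated production scale."""
    base = base or SimulationParams()
    params = replace(
        base,
        cycle=calibrated_cycle_params(mechanism, base.cycle),
        signal=scaled_signal_params(mechanism, target_density, base.signal))
    scenario = Scenario(initial_cell_count=initial_cell_count,
                        initial_melanocyte_fraction=float(target_density))
    return params, scenario
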