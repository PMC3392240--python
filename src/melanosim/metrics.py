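"""Spatial-evenness statistics of the melanocyte pattern.

Two statistics quantify how evenly the melanocytes are distributed:

* the fraction of melanocytes with more than three melanocyte neighbours
  (neighbour = centre-to-centre distance at most one cell diameter, 20 µm) —
  clumping raises it, even spacing suppresses it;
* the relative standard deviation (relsd) of nearest-melanocyte distances:
  SD divided by mean, time-averaged over the final simulated day.  A
  perfect lattice gives 0; complete spatial randomness gives ≈ 0.52
  (the Rayleigh value sqrt(4/π − 1)); lower is more even.

Both use interior focal points with a global neighbour search: only
melanocytes inside the central observation window enter the statistic, but
neighbours/nearest cells are sought over the whole dish, which removes the
upward bias a window-only search would put on border cells' distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .core import CELL_DIAMETER, Dish, SimulationState, in_observation_area


@dataclass(frozen=True)
class MetricsRecord:
    """Per-iteration observation-window measurements."""

    iteration: int
    n_cells_obs: int
    melanocyte_count_obs: int
    melanocyte_density: float  # melanocyte fraction of cells in the window
    n_with_many_neighbors: Optional[int]
    neighbor_ratio: Optional[float]
    mdist: Optional[float]
    sddist: Optional[float]


@dataclass(frozen=True)
class ReplicateSummary:
    """Endpoint statistics of one replicate, time-averaged over the final
    window (default 48 iterations = 24 h)."""

    neighbor_ratio: Optional[float]
    relsd: Optional[float]
    melanocyte_density: float
    mechanism: str = ""
    target_density: float = float("nan")
    seed: int = -1


def _mel_xy(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    pop = state.population
    mel = pop.xy[pop.is_mel()]
    obs = in_observation_area(mel, state.dish) if len(mel) else \
        np.zeros(0, dtype=bool)
    return mel, obs


def melanocyte_neighbor_ratio(state: SimulationState,
                              dish: Dish | None = None,
                              min_neighbors_exclusive: int = 3
                              ) -> tuple[Optional[int], Optional[float]]:
    """(count, ratio) of observation-window melanocytes with more than
    ``min_neighbors_exclusive`` melanocyte neighbours.

    Neighbour = centre-to-centre distance ≤ 20 µm.  Focal melanocytes must
    lie inside the observation window, but every melanocyte on the dish
    counts as a potential neighbour.  With zero melanocytes in the window
    the ratio is undefined and (None, None) is returned.  Set
    ``min_neighbors_exclusive=2`` for the "three or more" counting variant.
    """
    if dish is not None:
        state = SimulationState(state.iteration, state.population,
                                state.rng, dish)
    mel, obs = _mel_xy(state)
    n_obs = int(obs.sum())
    if n_obs == 0:
        return None, None
    tree = cKDTree(mel)
    counts = np.array([len(tree.query_ball_point(p, CELL_DIAMETER)) - 1
                       for p in mel[obs]])
    many = int((counts > min_neighbors_exclusive).sum())
    return many, many / n_obs


def nearest_distance_stats(state: SimulationState,
                           dish: Dish | None = None
                           ) -> tuple[Optional[float], Optional[float]]:
    """(mdist, sddist): mean and population SD of each observation-window
    melanocyte's distance to its nearest other melanocyte anywhere on the
    dish.  Undefined (None, None) with fewer than two melanocytes on the
    dish or none in the window."""
    if dish is not None:
        state = SimulationState(state.iteration, state.population,
                                state.rng, dish)
    mel, obs = _mel_xy(state)
    if len(mel) < 2 or not obs.any():
        return None, None
    tree = cKDTree(mel)
    d, _ = tree.query(mel[obs], k=2)
    nn = d[:, 1]
    return float(nn.mean()), float(nn.std())


def collect_record(state: SimulationState,
                   min_neighbors_exclusive: int = 3) -> MetricsRecord:
    """All per-iteration measurements for one state."""
    pop = state.population
    obs_all = in_observation_area(pop.xy, state.dish) if len(pop) else \
        np.zeros(0, dtype=bool)
    n_obs = int(obs_all.sum())
    n_mel_obs = int((obs_all & pop.is_mel()).sum())
    density = n_mel_obs / n_obs if n_obs else float("nan")
    many, ratio = melanocyte_neighbor_ratio(
        state, min_neighbors_exclusive=min_neighbors_exclusive)
    mdist, sddist = nearest_distance_stats(state)
    return MetricsRecord(state.iteration, n_obs, n_mel_obs, density,
                         many, ratio, mdist, sddist)


def window_summary(series: Sequence[MetricsRecord],
                   window: int = 48) -> ReplicateSummary:
    """Endpoint summary over the last ``window`` records.

    relsd = mean(sddist over the window) / mean(mdist over the window) — a
    ratio of window means, matching how the endpoint statistic is defined;
    the neighbour ratio is likewise the ratio of window-mean counts
    (equivalently mean count over mean window population)."""
    if len(series) < window:
        raise ValueError(f"series of length {len(series)} shorter than "
                         f"window {window}")
    tail = series[-window:]
    sddists = [r.sddist for r in tail if r.sddist is not None]
    mdists = [r.mdist for r in tail if r.mdist is not None]
    relsd = (float(np.mean(sddists)) / float(np.mean(mdists))
             if mdists and sddists and np.mean(mdists) > 0 else None)
    many = [r.n_with_many_neighbors for r in tail
            if r.n_with_many_neighbors is not None]
    tot = [r.melanocyte_count_obs for r in tail
           if r.n_with_many_neighbors is not None]
    ratio = (float(np.sum(many)) / float(np.sum(tot))
             if tot and np.sum(tot) > 0 else None)
    density = float(np.mean([r.melanocyte_density for r in tail]))
    return ReplicateSummary(neighbor_ratio=ratio, relsd=relsd,
                            melanocyte_density=density)


def ks_compare(group_a: Sequence[float], group_b: Sequence[float]
               ) -> tuple[float, float, str]:
    """Two-sample Kolmogorov–Smirnov comparison of two replicate groups.

    Returns (D statistic, p-value, stars) with stars '**' for p < 0.01,
    '*' for p < 0.05, '' otherwise."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(b)) < 3:
        import warnings
        warnings.warn("fewer than 3 values per group; KS p-value unreliable",
                      stacklevel=2)
    res = ks_2samp(a, b, method="exact" if max(len(a), len(b)) <= 25
                   else "auto")
    stars = "**" if res.pvalue < 0.01 else ("*" if res.pvalue < 0.05 else "")
    return float(res.statistic), float(res.pvalue), stars


def csr_relsd_baseline(n_melanocytes: int, dish: Dish | None = None,
                       n_draws: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo relsd of complete spatial randomness.

    Places ``n_melanocytes`` points uniformly over the dish ``n_draws``
    times and returns the mean sddist/mdist over draws, computed with the
    same window/global-neighbour convention as the simulation metric.  This
    is the null value against which "more even than random" is judged; for
    large n it approaches the Rayleigh value sqrt(4/π − 1) ≈ 0.523.
    """
    dish = dish or Dish()
    rng = np.random.default_rng(seed)
    lo, hi = 0.0, dish.side
    vals = []
    for _ in range(n_draws):
        xy = rng.uniform(lo, hi, size=(n_melanocytes, 2))
        obs = in_observation_area(xy, dish)
        if len(xy) < 2 or not obs.any():
            continue
        tree = cKDTree(xy)
        d, _ = tree.query(xy[obs], k=2)
        nn = d[:, 1]
        m = nn.mean()
        if m > 0:
            vals.append(nn.std() / m)
    if not vals:
        raise ValueError("no valid draws; too few melanocytes")
    return float(np.mean(vals))
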