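"""Evenness statistics: neighbour ratio, nearest-distance stats, window
summaries, the CSR baseline and the KS comparison."""

import itertools
import math

import numpy as np
import pytest

from melanosim.core import Cell, CellType, Dish, SimulationState
from melanosim.metrics import (MetricsRecord, collect_record,
                               csr_relsd_baseline, ks_compare,
                               melanocyte_neighbor_ratio,
                               nearest_distance_stats, window_summary)

from conftest import make_cell


def state_of(cells, dish=None):
    return SimulationState.from_cells(cells, seed=0, dish=dish or Dish())


def brute_neighbor_ratio(cells, dish, more_than=3):
    mel = [c for c in cells if c.type == CellType.MELANOCYTE]
    lo, hi = dish.observation_margin, dish.side - dish.observation_margin
    inside = [c for c in mel if lo <= c.x <= hi and lo <= c.y <= hi]
    if not inside:
        return None
    many = 0
    for c in inside:
        k = sum(1 for o in mel if o.id != c.id
                and math.hypot(o.x - c.x, o.y - c.y) <= 20.0)
        if k > more_than:
            many += 1
    return many / len(inside)


def brute_nearest_stats(cells, dish):
    mel = [c for c in cells if c.type == CellType.MELANOCYTE]
    lo, hi = dish.observation_margin, dish.side - dish.observation_margin
    inside = [c for c in mel if lo <= c.x <= hi and lo <= c.y <= hi]
    if len(mel) < 2 or not inside:
        return None, None
    dists = [min(math.hypot(o.x - c.x, o.y - c.y)
                 for o in mel if o.id != c.id) for c in inside]
    return float(np.mean(dists)), float(np.std(dists))


class TestNeighborRatio:
    def test_isolated_corner_melanocytes(self, dish):
        cells = [make_cell(i, 150 + 100 * (i % 2), 150 + 100 * (i // 2))
                 for i in range(4)]
        _, ratio = melanocyte_neighbor_ratio(state_of(cells))
        assert ratio == 0.0

    def test_hexagonal_cluster_of_seven(self, dish):
        # centre has 6 neighbours (> 3), ring cells have 3 (not > 3)
        cells = [make_cell(0, 200, 200)]
        for k in range(6):
            a = k * np.pi / 3
            cells.append(make_cell(k + 1, 200 + 20 * np.cos(a),
                                   200 + 20 * np.sin(a)))
        many, ratio = melanocyte_neighbor_ratio(state_of(cells))
        assert many == 1
        assert ratio == pytest.approx(1 / 7)

    def test_inclusive_variant_counts_ring_cells(self, dish):
        cells = [make_cell(0, 200, 200)]
        for k in range(6):
            a = k * np.pi / 3
            cells.append(make_cell(k + 1, 200 + 20 * np.cos(a),
                                   200 + 20 * np.sin(a)))
        many, ratio = melanocyte_neighbor_ratio(state_of(cells),
                                                min_neighbors_exclusive=2)
        assert many == 7 and ratio == 1.0

    def test_neighbors_outside_observation_area_still_count(self, dish):
        # focal at (55, 200): 4 contacts, one of them outside the window
        cells = [make_cell(0, 55, 200), make_cell(1, 35, 200),
                 make_cell(2, 75, 200), make_cell(3, 55, 180),
                 make_cell(4, 55, 220)]
        many, ratio = melanocyte_neighbor_ratio(state_of(cells))
        # focal has 4 neighbours (> 3); the cell at (35, 200) is outside
        # the window so the denominator is 4
        assert many == 1
        assert ratio == pytest.approx(1 / 4)

    def test_no_melanocytes_in_window_is_missing(self, dish):
        cells = [make_cell(0, 10, 10), make_cell(1, 20, 10)]
        assert melanocyte_neighbor_ratio(state_of(cells)) == (None, None)


class TestNearestDistances:
    def test_lattice_has_zero_spread(self):
        from melanosim.fixtures import lattice_melanocytes
        mdist, sddist = nearest_distance_stats(
            state_of(lattice_melanocytes(5, 40.0)))
        assert mdist == pytest.approx(40.0)
        assert sddist == pytest.approx(0.0, abs=1e-9)

    def test_three_collinear_hand_case(self):
        cells = [make_cell(0, 100, 200), make_cell(1, 130, 200),
                 make_cell(2, 190, 200)]
        mdist, sddist = nearest_distance_stats(state_of(cells))
        # nearest distances (30, 30, 60): mean 40, population SD sqrt(200)
        assert mdist == pytest.approx(40.0)
        assert sddist == pytest.approx(np.sqrt(200.0))

    def test_single_window_melanocyte_with_outside_neighbor(self):
        # only (60, 200) lies in the window; its nearest melanocyte sits
        # outside the window at 45 µm and still counts
        cells = [make_cell(0, 60, 200), make_cell(1, 15, 200)]
        mdist, sddist = nearest_distance_stats(state_of(cells))
        assert mdist == pytest.approx(45.0)
        assert sddist == 0.0

    def test_fewer_than_two_melanocytes_is_missing(self):
        assert nearest_distance_stats(
            state_of([make_cell(0, 200, 200)])) == (None, None)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_oracles(self, random_cells, seed):
        cells = random_cells(150, mel_fraction=0.4, seed=seed)
        st = state_of(cells)
        dish = Dish()
        _, ratio = melanocyte_neighbor_ratio(st)
        assert ratio == pytest.approx(brute_neighbor_ratio(cells, dish))
        mdist, sddist = nearest_distance_stats(st)
        bm, bs = brute_nearest_stats(cells, dish)
        assert mdist == pytest.approx(bm)
        assert sddist == pytest.approx(bs)


class TestWindowSummary:
    @staticmethod
    def rec(i, mdist, sddist, many=0, n=10):
        return MetricsRecord(i, 100, n, n / 100, many, many / n, mdist,
                             sddist)

    def test_constant_series_reproduces_constants(self):
        series = [self.rec(i, 40.0, 8.0, many=2) for i in range(60)]
        s = window_summary(series, window=48)
        assert s.relsd == pytest.approx(0.2)
        assert s.neighbor_ratio == pytest.approx(0.2)

    def test_ratio_of_window_means(self):
        series = [self.rec(i, 30.0, 6.0) for i in range(24)] + \
                 [self.rec(i, 50.0, 10.0) for i in range(24, 48)]
        s = window_summary(series, window=48)
        assert s.relsd == pytest.approx(np.mean([6.0, 10.0]) /
                                        np.mean([30.0, 50.0]))

    def test_window_equal_to_series_length_uses_everything(self):
        series = [self.rec(i, 40.0, 4.0) for i in range(10)]
        assert window_summary(series, window=10).relsd == pytest.approx(0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            window_summary([self.rec(0, 40.0, 8.0)], window=48)

    def test_relsd_scale_invariance(self, random_cells):
        cells = random_cells(80, mel_fraction=0.5, seed=11)
        m1, s1 = nearest_distance_stats(state_of(cells))
        scaled = [Cell(c.id, c.type, c.x * 2, c.y * 2) for c in cells]
        m2, s2 = nearest_distance_stats(state_of(scaled, dish=Dish(side=800,
                                        observation_margin=100)))
        assert s1 / m1 == pytest.approx(s2 / m2, rel=1e-9)


def exact_ks_pvalue(a, b):
    """Enumerate all label assignments of the pooled sample (exact
    two-sample KS null for small n) and return P(D >= D_obs)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def ks_stat(x, y):
        allv = np.sort(np.concatenate([x, y]))
        cx = np.searchsorted(np.sort(x), allv, side="right") / len(x)
        cy = np.searchsorted(np.sort(y), allv, side="right") / len(y)
        return np.max(np.abs(cx - cy))

    d_obs = ks_stat(a, b)
    count = total = 0
    idx = range(n + m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        d = ks_stat(pooled[mask], pooled[~mask])
        total += 1
        if d >= d_obs - 1e-12:
            count += 1
    return count / total


class TestKSCompare:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        d, p, stars = ks_compare(a, a)
        assert d == 0.0 and p == 1.0 and stars == ""

    def test_disjoint_supports_are_highly_significant(self):
        a = list(np.arange(12, dtype=float))
        b = list(np.arange(100, 112, dtype=float))
        d, p, stars = ks_compare(a, b)
        assert d == 1.0 and p < 0.01 and stars == "**"

    def test_matches_exact_enumeration_on_small_samples(self):
        a = [0.31, 0.25, 0.41, 0.18, 0.35]
        b = [0.52, 0.47, 0.39, 0.58]
        d, p, _ = ks_compare(a, b)
        assert p == pytest.approx(exact_ks_pvalue(a, b), abs=1e-9)

    def test_tiny_groups_warn_but_compute(self):
        with pytest.warns(UserWarning):
            _, p, _ = ks_compare([1.0, 2.0], [3.0, 4.0])
        assert 0 <= p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestCSRBaseline:
    def test_approaches_rayleigh_value_for_large_n(self):
        # Poisson nearest-neighbour distances are Rayleigh:
        # sd/mean = sqrt(4/pi - 1) ~ 0.523
        val = csr_relsd_baseline(300, n_draws=150, seed=1)
        assert val == pytest.approx(np.sqrt(4 / np.pi - 1), abs=0.05)

    def test_interior_focus_removes_border_inflation(self, rng):
        # computing nearest distances only within the window inflates the
        # statistic for border points; the global search must not
        from melanosim.core import in_observation_area
        from scipy.spatial import cKDTree
        dish = Dish()
        diffs = []
        for _ in range(100):
            xy = rng.uniform(0, 400, size=(120, 2))
            obs = in_observation_area(xy, dish)
            tree_all = cKDTree(xy)
            d_all, _ = tree_all.query(xy[obs], k=2)
            tree_win = cKDTree(xy[obs])
            d_win, _ = tree_win.query(xy[obs], k=2)
            diffs.append(d_win[:, 1].mean() - d_all[:, 1].mean())
        assert np.mean(diffs) > 0  # window-only search is biased upward


class TestCollectRecord:
    def test_counts_partition_and_density(self, random_cells):
        cells = random_cells(100, mel_fraction=0.3, seed=2)
        rec = collect_record(state_of(cells))
        assert 0 <= rec.melanocyte_count_obs <= rec.n_cells_obs
        assert rec.melanocyte_density == pytest.approx(
            rec.melanocyte_count_obs / rec.n_cells_obs)
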