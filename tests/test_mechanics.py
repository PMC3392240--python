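"""Chemotaxis, random walk, repulsion, adhesion and wall contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melanosim.core import Dish
from melanosim.mechanics import (MechanicsParams, apply_adhesion,
                                 chemotaxis_vector, clamp_to_dish, lens_area,
                                 resolve_overlaps, ta_random_step)


@pytest.fixture
def mpar():
    return MechanicsParams(migration_gain=1.0, max_step=100.0)


class TestChemotaxis:
    def test_uniform_field_gives_zero_vector(self, mpar):
        pos = np.array([0.0, 0.0])
        nbr = np.array([[20.0, 0.0], [-20.0, 0.0], [0.0, 20.0]])
        lev = np.array([3.0, 3.0, 3.0])
        v = chemotaxis_vector(pos, nbr, lev, "attract", mpar)
        np.testing.assert_array_equal(v, [0.0, 0.0])

    def test_empty_neighbor_list_gives_zero_vector(self, mpar):
        v = chemotaxis_vector(np.zeros(2), np.zeros((0, 2)), np.zeros(0),
                              "attract", mpar)
        np.testing.assert_array_equal(v, [0.0, 0.0])

    def test_two_neighbor_hand_case_attract(self, mpar):
        # east level 4, west level 1, gain 1: u_max - u_min = 2*east,
        # magnitude 2*(4-1) = 6 µm pointing east
        pos = np.array([0.0, 0.0])
        nbr = np.array([[20.0, 0.0], [-20.0, 0.0]])
        lev = np.array([4.0, 1.0])
        v = chemotaxis_vector(pos, nbr, lev, "attract", mpar)
        np.testing.assert_allclose(v, [6.0, 0.0], atol=1e-12)

    def test_repel_mode_is_antisymmetric(self, mpar):
        pos = np.array([0.0, 0.0])
        nbr = np.array([[20.0, 0.0], [-20.0, 0.0]])
        lev = np.array([4.0, 1.0])
        va = chemotaxis_vector(pos, nbr, lev, "attract", mpar)
        vr = chemotaxis_vector(pos, nbr, lev, "repel", mpar)
        np.testing.assert_allclose(vr, -va, atol=1e-12)
        np.testing.assert_allclose(vr, [-6.0, 0.0], atol=1e-12)

    def test_magnitude_capped_at_max_step(self):
        p = MechanicsParams(migration_gain=10.0, max_step=2.0)
        pos = np.zeros(2)
        nbr = np.array([[20.0, 0.0], [-20.0, 0.0]])
        lev = np.array([50.0, 0.0])
        v = chemotaxis_vector(pos, nbr, lev, "attract", p)
        assert np.linalg.norm(v) == pytest.approx(2.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_rotation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = MechanicsParams(migration_gain=0.7, max_step=5.0)
        k = int(rng.integers(1, 8))
        nbr = rng.uniform(-30, 30, size=(k, 2))
        lev = rng.uniform(0, 5, size=k)
        phi = float(rng.uniform(0, 2 * np.pi))
        R = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        v = chemotaxis_vector(np.zeros(2), nbr, lev, "attract", p)
        v_rot = chemotaxis_vector(np.zeros(2), nbr @ R.T, lev, "attract", p)
        np.testing.assert_allclose(v_rot, R @ v, atol=1e-9)
        assert np.linalg.norm(v) <= p.max_step + 1e-12

    def test_tie_break_prefers_lowest_id(self, mpar):
        # two neighbours share the max level; the lower id wins
        pos = np.zeros(2)
        nbr = np.array([[20.0, 0.0], [0.0, 20.0], [-20.0, 0.0]])
        lev = np.array([5.0, 5.0, 1.0])
        ids = np.array([7, 3, 9])
        v = chemotaxis_vector(pos, nbr, lev, "attract", mpar,
                              neighbor_ids=ids)
        # max is the id-3 neighbour (north), min the west one:
        # Δ·(u_max − u_min) = 4·((0,1) − (−1,0)) = (4, 4)
        np.testing.assert_allclose(v, [4.0, 4.0], atol=1e-12)


class TestRandomWalk:
    def test_zero_magnitude_gives_zero_vector(self, rng):
        p = MechanicsParams(ta_random_step=0.0)
        np.testing.assert_array_equal(ta_random_step(p, rng), [0.0, 0.0])

    def test_isotropy_of_many_draws(self, rng):
        p = MechanicsParams(ta_random_step=1.0)
        draws = np.array([ta_random_step(p, rng) for _ in range(10_000)])
        np.testing.assert_allclose(np.linalg.norm(draws, axis=1), 1.0)
        se = 1.0 / np.sqrt(2 * len(draws))  # per-axis SD is 1/sqrt(2)
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se)


class TestOverlapResolution:
    def test_lens_area_closed_form_matches_monte_carlo(self, rng):
        r, d = 10.0, 10.0
        area = float(lens_area(np.array([d]), r)[0])
        pts = rng.uniform(-r, r, size=(200_000, 2))
        inside = (np.linalg.norm(pts, axis=1) <= r) & \
                 (np.linalg.norm(pts - [d, 0.0], axis=1) <= r)
        mc = inside.mean() * (2 * r) ** 2
        assert area == pytest.approx(mc, rel=0.02)
        assert lens_area(np.array([2 * r]), r)[0] == 0.0

    def test_non_overlapping_and_tangent_pairs_unchanged(self):
        p = MechanicsParams()
        xy = np.array([[0.0, 0.0], [20.0, 0.0], [100.0, 100.0]])
        out = resolve_overlaps(xy, 10.0, p)
        np.testing.assert_array_equal(out, xy)

    def test_overlapping_pair_moves_apart_symmetrically(self):
        p = MechanicsParams(relaxation_iterations=50)
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = resolve_overlaps(xy, 10.0, p)
        d = np.linalg.norm(out[1] - out[0])
        assert d > 10.0  # strictly pushed apart
        # displacement is symmetric about the midpoint
        mid = 0.5 * (out[0] + out[1])
        np.testing.assert_allclose(mid, [5.0, 0.0], atol=1e-9)

    def test_residual_overlap_small_on_dense_configurations(self, rng):
        p = MechanicsParams(relaxation_iterations=150)
        xy = rng.uniform(0, 400, size=(300, 2))  # ~59% coverage, packable
        out = resolve_overlaps(xy, 10.0, p, rng=rng)
        from melanosim.core import neighbor_pairs
        pairs = neighbor_pairs(out, 20.0)
        if len(pairs):
            dist = np.linalg.norm(out[pairs[:, 1]] - out[pairs[:, 0]], axis=1)
            assert (20.0 - dist).max() < 0.5

    def test_coincident_centers_separate(self, rng):
        p = MechanicsParams(relaxation_iterations=10)
        xy = np.array([[50.0, 50.0], [50.0, 50.0]])
        out = resolve_overlaps(xy, 10.0, p, rng=rng)
        assert np.linalg.norm(out[1] - out[0]) > 0


class TestAdhesion:
    def test_out_of_range_pair_untouched(self):
        p = MechanicsParams()
        xy = np.array([[0.0, 0.0], [35.0, 0.0]])  # gap 15 > 10
        np.testing.assert_array_equal(apply_adhesion(xy, 10.0, p), xy)

    def test_maximal_pull_at_range_boundary(self):
        p = MechanicsParams(adhesion_range=10.0, adhesion_gain=0.5)
        xy = np.array([[0.0, 0.0], [30.0, 0.0]])  # gap exactly 10
        out = apply_adhesion(xy, 10.0, p)
        gap = np.linalg.norm(out[1] - out[0]) - 20.0
        assert gap == pytest.approx(10.0 - 0.5)

    def test_tangent_pair_not_pulled(self):
        p = MechanicsParams()
        xy = np.array([[0.0, 0.0], [20.0, 0.0]])
        np.testing.assert_array_equal(apply_adhesion(xy, 10.0, p), xy)

    def test_never_pulls_past_tangency(self):
        p = MechanicsParams(adhesion_range=10.0, adhesion_gain=50.0)
        xy = np.array([[0.0, 0.0], [20.5, 0.0]])
        out = apply_adhesion(xy, 10.0, p)
        assert np.linalg.norm(out[1] - out[0]) >= 20.0 - 1e-9


class TestWalls:
    def test_interior_point_unchanged(self, dish):
        np.testing.assert_array_equal(
            clamp_to_dish(np.array([[200.0, 200.0]]), dish, 10.0),
            [[200.0, 200.0]])

    def test_outside_point_clamped_to_wall_contact(self, dish):
        out = clamp_to_dish(np.array([[-5.0, 200.0]]), dish, 10.0)
        np.testing.assert_array_equal(out, [[10.0, 200.0]])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        dish = Dish()
        p = rng.uniform(-100, 500, size=(10, 2))
        once = clamp_to_dish(p, dish, 10.0)
        np.testing.assert_array_equal(clamp_to_dish(once, dish, 10.0), once)
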