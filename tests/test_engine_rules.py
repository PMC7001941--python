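"""Elementary motion/adhesion/division rules of the agent-based model."""

import numpy as np
import pytest

from cellagg.engine import (
    AbmConfig,
    FluxSpec,
    aggregate_step_length,
    attempt_division,
    compaction_halfwidth_deg,
    init_world,
    intra_step_length,
    min_center_distance,
    no_detach_accept,
    propose_direction,
    truncated_move,
)
from cellagg.space import BoxSpec, min_image_vector


@pytest.fixture
def cfg100():
    return AbmConfig(
        n_initial=4, cell_diameter=10.0, step_length=6.0, alpha_max=0.6,
        box=BoxSpec(100.0), proliferation_rate=0.0,
    )


class TestStepLengths:
    def test_min_center_distance(self):
        cfg = AbmConfig(n_initial=1, cell_diameter=13.2, alpha_max=0.7)
        assert np.isclose(min_center_distance(cfg), 3.96)
        assert np.isclose(
            min_center_distance(AbmConfig(n_initial=1, cell_diameter=5.0, alpha_max=0.0)), 5.0
        )

    @pytest.mark.parametrize("n,expected", [(0, 6.0), (1, 3.0), (3, 0.6)])
    def test_intra_step(self, n, expected):
        assert np.isclose(intra_step_length(6.0, n), expected)

    def test_intra_step_decreasing(self):
        vals = [intra_step_length(6.0, n) for n in range(8)]
        assert np.all(np.diff(vals) < 0)

    def test_intra_step_negative_n_rejected(self):
        with pytest.raises(ValueError):
            intra_step_length(6.0, -1)

    @pytest.mark.parametrize("N,expected", [(1, 6.0), (4, 1.5)])
    def test_aggregate_step(self, N, expected):
        assert np.isclose(aggregate_step_length(6.0, N), expected)

    def test_aggregate_step_monotone(self):
        vals = [aggregate_step_length(6.0, N) for N in range(1, 20)]
        assert np.all(np.diff(vals) < 0)
        with pytest.raises(ValueError):
            aggregate_step_length(6.0, 0)


class TestCompactionSector:
    def test_tiny_aggregate_full_circle(self):
        assert np.isclose(compaction_halfwidth_deg(0), 180.0)

    def test_large_aggregate_half_plane_limit(self):
        assert np.isclose(compaction_halfwidth_deg(1e4), 90.0, atol=1e-4)

    def test_n40_value(self):
        assert np.isclose(compaction_halfwidth_deg(40), 90.0 * (1 + np.exp(-1.0)))

    def test_strictly_decreasing_to_90(self):
        n = np.arange(0, 500)
        hw = compaction_halfwidth_deg(n)
        assert np.all(np.diff(hw) < 0)
        assert np.all(hw > 90.0)


class TestProposeDirection:
    def test_compaction_sector_support(self, cfg100, rng):
        # cell west of the com: bias centered due east (0 deg)
        p = np.array([40.0, 50.0])
        com = np.array([60.0, 50.0])
        hw = compaction_halfwidth_deg(2)
        for _ in range(2000):
            ang = propose_direction(p, 2, com, cfg100, rng)
            delta = (ang - 0.0 + 180.0) % 360.0 - 180.0
            assert abs(delta) <= hw + 1e-9

    def test_compaction_off_uniform(self, rng):
        from scipy import stats

        cfg = AbmConfig(
            n_initial=4, cell_diameter=10.0, compaction_enabled=False, box=BoxSpec(100.0)
        )
        draws = np.array(
            [
                propose_direction(np.zeros(2), 3, np.array([5.0, 5.0]), cfg, rng)
                for _ in range(10_000)
            ]
        )
        assert stats.kstest(draws / 360.0, "uniform").pvalue > 0.01

    def test_individual_with_flux_halfplane(self, rng):
        cfg = AbmConfig(
            n_initial=4, cell_diameter=10.0, flux=FluxSpec(enabled=True, direction=0.0),
            box=BoxSpec(100.0),
        )
        for _ in range(2000):
            ang = propose_direction(np.zeros(2), 1, None, cfg, rng)
            assert np.cos(np.radians(ang)) >= -1e-12

    def test_missing_com_rejected(self, cfg100, rng):
        with pytest.raises(ValueError):
            propose_direction(np.zeros(2), 3, None, cfg100, rng)


class TestTruncatedMove:
    def test_empty_neighborhood_full_step(self, box100):
        p = truncated_move(np.array([10.0, 10.0]), 0.0, 5.0, np.empty((0, 2)), 4.0, box100)
        assert np.allclose(p, [15.0, 10.0])

    def test_blocker_ahead_stops_at_contact(self, box100):
        # blocker 10 ahead, dmin 4 -> travel 6
        p = truncated_move(
            np.array([10.0, 50.0]), 0.0, 10.0, np.array([[20.0, 50.0]]), 4.0, box100
        )
        assert np.isclose(p[0], 16.0, atol=1e-6)
        assert np.isclose(
            np.linalg.norm(min_image_vector(p, np.array([20.0, 50.0]), box100)), 4.0,
            atol=1e-6,
        )

    def test_blocker_behind_ignored(self, box100):
        p = truncated_move(
            np.array([10.0, 50.0]), 0.0, 5.0, np.array([[5.0, 50.0]]), 4.0, box100
        )
        assert np.allclose(p, [15.0, 50.0])

    def test_at_contact_approaching_stays(self, box100):
        p0 = np.array([10.0, 50.0])
        p = truncated_move(p0, 0.0, 5.0, np.array([[14.0, 50.0]]), 4.0, box100)
        assert np.allclose(p, p0)

    def test_never_violates_dmin_randomized(self, rng, box100):
        dmin = 3.0
        for _ in range(300):
            p0 = rng.uniform(0, 100, 2)
            others = rng.uniform(0, 100, (8, 2))
            v = min_image_vector(p0, others, box100)
            others = others[np.linalg.norm(v, axis=1) >= dmin]
            p1 = truncated_move(
                p0, rng.uniform(0, 360), rng.uniform(0, 8), others, dmin, box100
            )
            if len(others):
                dists = np.linalg.norm(min_image_vector(p1, others, box100), axis=1)
                assert dists.min() >= dmin - 1e-9


class TestNoDetach:
    def test_isolated_always_accepts(self, box100):
        assert no_detach_accept(
            np.zeros(2), np.array([50.0, 50.0]), np.empty((0, 2)), 10.0, box100
        )

    def test_losing_a_neighbor_rejected(self, box100):
        others = np.array([[9.0, 50.0], [27.0, 50.0]])
        p = np.array([18.0, 50.0])  # touches both at distance 9 <= d=10
        prop = np.array([9.0, 59.5])  # keeps only the first
        assert not no_detach_accept(p, prop, others, 10.0, box100)

    def test_swapping_neighbors_accepted(self, box100):
        others = np.array([[10.0, 50.0], [40.0, 50.0]])
        p = np.array([18.0, 50.0])  # neighbor: first only
        prop = np.array([32.0, 50.0])  # neighbor: second only
        assert no_detach_accept(p, prop, others, 10.0, box100)


class TestAttemptDivision:
    def test_zero_rate_never_divides(self, rng, box100):
        cfg = AbmConfig(n_initial=1, cell_diameter=10.0, proliferation_rate=0.0, box=box100)
        assert all(
            attempt_division(np.array([50.0, 50.0]), np.empty((0, 2)), cfg, rng) is None
            for _ in range(500)
        )

    def test_isolated_mother_daughter_at_distance_d(self, rng, box100):
        cfg = AbmConfig(n_initial=1, cell_diameter=10.0, proliferation_rate=1.0, box=box100)
        mother = np.array([50.0, 50.0])
        for _ in range(1000):
            daughter = attempt_division(mother, np.empty((0, 2)), cfg, rng)
            assert daughter is not None
            assert np.isclose(
                np.linalg.norm(min_image_vector(mother, daughter, box100)), 10.0
            )

    def test_enclosed_mother_always_aborts(self, rng, box100):
        # ring of 12 cells at radius d: every candidate daughter position on
        # the circle of radius d is within dmin of some ring cell
        d = 10.0
        cfg = AbmConfig(
            n_initial=1, cell_diameter=d, proliferation_rate=1.0, alpha_max=0.7, box=box100
        )
        mother = np.array([50.0, 50.0])
        ring = np.array(
            [
                mother + d * np.array([np.cos(a), np.sin(a)])
                for a in np.radians(np.arange(0, 360, 30))
            ]
        )
        assert all(
            attempt_division(mother, ring, cfg, rng) is None for _ in range(500)
        )


class TestInitWorld:
    def test_single_cell(self):
        w = init_world(AbmConfig(n_initial=1, seed=3))
        assert w.n_cells == 1
        assert np.all((w.positions >= 0) & (w.positions < 842.24))

    def test_hardcore_satisfied_at_density(self):
        cfg = AbmConfig(n_initial=400, cell_diameter=13.2, alpha_max=0.7, seed=11)
        w = init_world(cfg)
        from scipy.spatial import cKDTree

        tree = cKDTree(w.positions, boxsize=cfg.box.side_length)
        assert len(tree.query_pairs(cfg.dmin - 1e-9)) == 0

    def test_seed_determinism(self):
        cfg = AbmConfig(n_initial=50, seed=21, box=BoxSpec(400.0))
        w1, w2 = init_world(cfg), init_world(cfg)
        assert np.array_equal(w1.positions, w2.positions)
        w3 = init_world(AbmConfig(n_initial=50, seed=22, box=BoxSpec(400.0)))
        assert not np.array_equal(w1.positions, w3.positions)

    def test_infeasible_density_reports_error(self):
        cfg = AbmConfig(
            n_initial=200, cell_diameter=13.2, alpha_max=0.0, box=BoxSpec(50.0), seed=1
        )
        with pytest.raises(RuntimeError, match="density"):
            init_world(cfg, max_attempts=2000)
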