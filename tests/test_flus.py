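"""Simulation core: Markov calibration/projection, suitability network
contracts, neighborhood counts against a loop oracle, adaptive inertia
arithmetic, CA allocation discipline and kappa validation."""

import numpy as np
import pytest

from pleconflict import (
    Raster,
    SynthConfig,
    TransitionMatrix,
    allocate,
    demand_km2_to_cells,
    evolve_landuse,
    fit_markov,
    gen_drivers,
    gen_landuse,
    kappa,
    neighborhood_effect,
    project_demand,
    train_suitability,
    update_inertia,
)


class TestMarkov:
    def test_identical_dates_give_identity(self, lu_small):
        tm = fit_markov(lu_small, lu_small)
        assert np.allclose(tm.P, np.eye(6))

    def test_rows_sum_to_one_exactly(self, cfg_small, drivers_small, lu_small):
        lu2 = evolve_landuse(
            lu_small, cfg_small.true_transition, cfg_small, drivers_small, seed=21
        )
        tm = fit_markov(lu_small, lu2)
        assert np.array_equal(tm.P.sum(axis=1), np.ones(6))

    def test_recovers_injected_matrix(self):
        cfg = SynthConfig(grid_shape=(200, 200), seed=23)
        drivers = gen_drivers(cfg)
        lu1 = gen_landuse(cfg, drivers)
        lu2 = evolve_landuse(lu1, cfg.true_transition, cfg, drivers, seed=24)
        tm = fit_markov(lu1, lu2)
        counts = lu1.class_counts()
        for a in range(6):
            if counts[a] == 0:
                continue
            for b in range(6):
                p = cfg.true_transition[a, b]
                se = np.sqrt(max(p * (1 - p), 1e-12) / counts[a])
                # largest-remainder placement adds at most one cell per entry
                assert abs(tm.P[a, b] - p) <= 3 * se + 1.0 / counts[a]

    def test_geometry_mismatch_rejected(self, lu_small):
        other = Raster(np.ones((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="geometry"):
            fit_markov(lu_small, other)


class TestDemandProjection:
    def test_identity_keeps_state(self):
        tm = TransitionMatrix(np.eye(6), interval_years=5)
        s = np.array([10, 20, 30, 5, 5, 0], dtype=float)
        assert np.allclose(project_demand(tm, s, 15), s)

    def test_single_step_is_matrix_vector_product(self):
        P = np.array([[0.8, 0.2], [0.1, 0.9]])
        tm = TransitionMatrix(P, interval_years=1)
        s = np.array([50.0, 50.0])
        assert np.allclose(project_demand(tm, s, 1), P.T @ s)

    def test_two_step_hand_example(self):
        P = np.array([[0.9, 0.1], [0.0, 1.0]])
        tm = TransitionMatrix(P, interval_years=1)
        out = project_demand(tm, np.array([100.0, 0.0]), 2)
        assert np.allclose(out, [81.0, 19.0])

    def test_total_conserved(self):
        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        tm = TransitionMatrix(P, interval_years=1)
        out = project_demand(tm, np.array([30.0, 70.0]), 7)
        assert out.sum() == pytest.approx(100.0)

    def test_non_multiple_horizon_rejected(self):
        tm = TransitionMatrix(np.eye(2), interval_years=5)
        with pytest.raises(ValueError, match="multiple"):
            project_demand(tm, np.array([1.0, 1.0]), 7)


class TestSuitability:
    @pytest.fixture(scope="class")
    def trained(self):
        cfg = SynthConfig(grid_shape=(100, 100), seed=31)
        drivers = gen_drivers(cfg)
        lu = gen_landuse(cfg, drivers)
        model = train_suitability(lu, drivers, seed=32)
        return lu, drivers, model

    def test_probabilities_sum_to_one(self, trained):
        _, drivers, model = trained
        sp = model.predict(drivers)
        assert np.allclose(sp.sum(axis=-1), 1.0, atol=1e-6)
        assert sp.min() >= 0.0 and sp.max() <= 1.0

    def test_learns_driver_class_relation(self, trained):
        """Class placement is a monotone function of the drivers by
        construction, so the trained network must beat 70% cell accuracy."""
        lu, drivers, model = trained
        sp = model.predict(drivers)
        pred = np.argmax(sp, axis=-1) + 1
        accuracy = np.mean(pred == lu.data)
        assert accuracy > 0.7

    def test_deterministic_under_fixed_seed(self, trained):
        lu, drivers, _ = trained
        a = train_suitability(lu, drivers, seed=33).predict(drivers)
        b = train_suitability(lu, drivers, seed=33).predict(drivers)
        assert np.array_equal(a, b)

    def test_oversized_sample_rejected(self, trained):
        lu, drivers, _ = trained
        with pytest.raises(ValueError, match="sample_n"):
            train_suitability(lu, drivers, sample_n=10**7)


class TestNeighborhood:
    def test_uniform_raster_interior(self):
        lu = Raster(np.full((9, 9), 3, dtype=np.uint8))
        omega = neighborhood_effect(lu, 3, window=3, weight=1.0)
        assert omega[4, 4] == pytest.approx(1.0)
        assert omega[0, 0] == pytest.approx(3 / 8)  # truncated corner window

    def test_absent_class_gives_zero(self):
        lu = Raster(np.full((5, 5), 2, dtype=np.uint8))
        assert np.all(neighborhood_effect(lu, 5, window=3) == 0)

    def test_even_window_rejected(self, lu_small):
        with pytest.raises(ValueError, match="odd"):
            neighborhood_effect(lu_small, 1, window=4)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_loop_oracle(self, lu_small, window):
        rng = np.random.default_rng(5)
        omega = neighborhood_effect(lu_small, 1, window=window, weight=0.56)
        rows, cols = lu_small.shape
        half = window // 2
        for _ in range(100):
            r, c = rng.integers(0, rows), rng.integers(0, cols)
            count = 0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        count += lu_small.data[rr, cc] == 1
            expected = count / (window**2 - 1) * 0.56
            assert omega[r, c] == pytest.approx(expected)


class TestInertia:
    def test_equal_gaps_unchanged(self):
        out = update_inertia(np.array([1.5]), np.array([7.0]), np.array([7.0]))
        assert out[0] == 1.5

    def test_worsening_negative_gap_printed_case(self):
        out = update_inertia(np.array([1.0]), np.array([-10.0]), np.array([-20.0]))
        assert out[0] == pytest.approx(0.5)

    def test_growing_positive_gap(self):
        out = update_inertia(np.array([1.0]), np.array([10.0]), np.array([20.0]))
        assert out[0] == pytest.approx(2.0)

    def test_zero_gap_treated_as_converged(self):
        out = update_inertia(np.array([2.0]), np.array([0.0]), np.array([5.0]))
        assert out[0] == 2.0

    def test_absolute_convention_ratchets_up(self):
        out = update_inertia(
            np.array([1.0]),
            np.array([-10.0]),
            np.array([-20.0]),
            convention="absolute",
        )
        assert out[0] == pytest.approx(0.5)
        out2 = update_inertia(
            np.array([1.0]), np.array([10.0]), np.array([20.0]), convention="absolute"
        )
        assert out2[0] == pytest.approx(2.0)


@pytest.fixture(scope="module")
def allocation_setup():
    cfg = SynthConfig(grid_shape=(80, 80), seed=41)
    drivers = gen_drivers(cfg)
    lu = gen_landuse(cfg, drivers)
    model = train_suitability(lu, drivers, seed=42)
    sp = model.predict(drivers)
    return lu, sp


class TestAllocation:
    def test_demand_equal_current_converges_immediately(self, allocation_setup):
        lu, sp = allocation_setup
        result = allocate(
            lu, sp, lu.class_counts(), np.ones((6, 6), int), np.ones(6), seed=1
        )
        assert result.converged and result.iterations == 1
        assert np.array_equal(result.landuse.data, lu.data)

    def test_blocked_source_class_never_shrinks(self, allocation_setup):
        """A cultivated row allowing only itself freezes cultivated cells."""
        lu, sp = allocation_setup
        allowance = np.ones((6, 6), int)
        allowance[0, :] = 0
        allowance[0, 0] = 1
        counts = lu.class_counts()
        demand = counts.copy()
        move = min(200, counts[0] // 2, counts[4])
        demand[0] -= move  # ask for fewer cultivated cells anyway
        demand[4] += move
        result = allocate(
            lu, sp, demand, allowance, np.ones(6), max_iter=30, seed=2
        )
        assert result.final_counts[0] >= counts[0]

    def test_no_forbidden_transition_in_trace(self, allocation_setup):
        lu, sp = allocation_setup
        allowance = np.eye(6, dtype=int)
        allowance[0, 4] = 1  # only cultivated -> construction allowed
        counts = lu.class_counts()
        demand = counts.copy()
        demand[0] -= 100
        demand[4] += 100
        result = allocate(lu, sp, demand, allowance, np.ones(6), seed=3)
        changed = lu.data != result.landuse.data
        pairs = set(
            zip(lu.data[changed].ravel(), result.landuse.data[changed].ravel())
        )
        assert pairs <= {(1, 5)}

    def test_restricted_cells_never_change(self, allocation_setup):
        lu, sp = allocation_setup
        rng = np.random.default_rng(11)
        restriction = rng.random(lu.shape) < 0.3
        counts = lu.class_counts()
        demand = counts.copy()
        demand[0] -= 150
        demand[4] += 150
        result = allocate(
            lu, sp, demand, np.ones((6, 6), int), np.ones(6),
            restriction=restriction, seed=4,
        )
        assert np.array_equal(
            lu.data[restriction], result.landuse.data[restriction]
        )

    def test_total_cells_conserved(self, allocation_setup):
        lu, sp = allocation_setup
        counts = lu.class_counts()
        demand = counts.copy()
        demand[0] -= 300
        demand[4] += 200
        demand[3] += 100
        result = allocate(lu, sp, demand, np.ones((6, 6), int), np.ones(6), seed=5)
        assert result.final_counts.sum() == counts.sum()

    def test_uniform_suitability_matches_demand_exactly(self, allocation_setup):
        """Degenerate closed form: with flat suitability, flat costs and a
        floor-dominated neighborhood, allocation must land on demand."""
        lu, _ = allocation_setup
        sp = np.full(lu.shape + (6,), 1 / 6)
        counts = lu.class_counts()
        demand = counts.copy()
        demand[0] -= 400
        demand[4] += 400
        result = allocate(lu, sp, demand, np.ones((6, 6), int), np.ones(6), seed=6)
        assert result.converged
        assert np.all(np.abs(result.residual) <= np.maximum(0.005 * demand, 10))

    def test_bad_demand_total_rejected(self, allocation_setup):
        lu, sp = allocation_setup
        demand = lu.class_counts() + 5
        with pytest.raises(ValueError, match="sum"):
            allocate(lu, sp, demand, np.ones((6, 6), int), np.ones(6))


class TestDemandConversion:
    def test_km2_to_cells_conserves_total(self, lu_small):
        demand = np.array([1453.65, 37.67, 0.15, 225.29, 297.63, 2.24])
        cells = demand_km2_to_cells(demand, lu_small)
        assert cells.sum() == int(lu_small.mask.sum())
        frac = demand / demand.sum()
        assert np.all(np.abs(cells - frac * cells.sum()) < 1.0)


class TestKappa:
    def test_identical_rasters(self, lu_small):
        assert kappa(lu_small, lu_small) == 1.0

    def test_symmetry(self, cfg_small, drivers_small, lu_small):
        lu2 = evolve_landuse(
            lu_small, cfg_small.true_transition, cfg_small, drivers_small, seed=51
        )
        assert kappa(lu_small, lu2) == pytest.approx(kappa(lu2, lu_small))

    def test_independent_rasters_near_zero(self):
        rng = np.random.default_rng(8)
        a = Raster(rng.integers(1, 5, size=(320, 320)).astype(np.uint8))
        b = Raster(rng.integers(1, 5, size=(320, 320)).astype(np.uint8))
        assert abs(kappa(a, b)) < 0.02

    def test_hand_confusion_matrix(self):
        """Confusion [[40,10],[10,40]]: po=0.8, pe=0.5, kappa=0.6."""
        a = np.repeat([1, 1, 2, 2], [40, 10, 10, 40]).astype(np.uint8)
        b = np.repeat([1, 2, 1, 2], [40, 10, 10, 40]).astype(np.uint8)
        assert kappa(Raster(a.reshape(10, 10)), Raster(b.reshape(10, 10))) == (
            pytest.approx(0.6)
        )
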