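"""Adaptive biasing: deposit contracts, interpolation, walls, convergence."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unspool.abmd import (
    BiasGrid,
    FloodingSchedule,
    deposit_bias,
    dropped_energy_profile,
    evaluate_bias,
    run_multiwalker,
    uniformity_metric,
    wall_energy,
)
from unspool.constants import kbt
from unspool.toy_systems import PotentialSpec, ScalarSystem

KT = kbt(300.0)


class TestBiasGrid:
    def test_node_count_and_range(self):
        grid = BiasGrid(20.0, 200.0, 1.0)
        assert len(grid.values) == 181
        assert grid.nodes[0] == 20.0 and grid.nodes[-1] == 200.0

    def test_empty_bias_evaluates_to_zero_everywhere(self):
        grid = BiasGrid(0.0, 10.0, 0.5)
        e, f = grid.evaluate(np.linspace(-5, 15, 41))
        assert np.all(e == 0) and np.all(f == 0)

    def test_node_values_are_interpolated_exactly(self, rng):
        grid = BiasGrid(0.0, 10.0, 0.5)
        grid.values[:] = rng.uniform(0, 5, len(grid.values))
        e, _ = grid.evaluate(grid.nodes)
        assert np.allclose(e, grid.values, rtol=1e-12)

    def test_force_matches_finite_difference(self, rng):
        grid = BiasGrid(0.0, 10.0, 0.5)
        grid.values[:] = rng.uniform(0, 5, len(grid.values))
        q = rng.uniform(1.0, 9.0, 200)
        h = 1e-7
        ep, _ = grid.evaluate(q + h)
        em, _ = grid.evaluate(q - h)
        num = (ep - em) / (2 * h)
        _, der = grid.evaluate(q)
        assert np.allclose(der, num, rtol=1e-6, atol=1e-6)

    def test_outside_range_is_zero(self):
        grid = BiasGrid(0.0, 10.0, 1.0)
        grid.values[:] = 3.0
        e, f = grid.evaluate(np.array([-0.1, 10.1]))
        assert np.all(e == 0) and np.all(f == 0)

    def test_csv_roundtrip(self, tmp_path, rng):
        grid = BiasGrid(5.0, 25.0, 0.5)
        grid.values[:] = rng.uniform(0, 2, len(grid.values))
        grid.to_csv(tmp_path / "bias.csv", meta={"tau": 100.0})
        back = BiasGrid.from_csv(tmp_path / "bias.csv")
        assert np.array_equal(back.values, grid.values)
        assert back.resolution == grid.resolution


class TestDeposit:
    def test_parked_walker_deposits_kbt_over_tau(self):
        grid = BiasGrid(0.0, 10.0, 0.25)
        schedule = FloodingSchedule(tau=100.0)
        dt = 0.01
        for _ in range(10000):  # total time = tau
            deposit_bias(grid, 5.0, dt, schedule)
        assert grid.integral == pytest.approx(KT, rel=1e-9)

    def test_zero_dt_is_a_no_op(self):
        grid = BiasGrid(0.0, 10.0, 1.0)
        deposit_bias(grid, 5.0, 0.0, FloodingSchedule(tau=10.0))
        assert grid.integral == 0.0

    def test_two_walkers_deposit_additively(self):
        one = BiasGrid(0.0, 10.0, 0.5)
        two = BiasGrid(0.0, 10.0, 0.5)
        schedule = FloodingSchedule(tau=50.0)
        t = 5.0
        for _ in range(500):
            deposit_bias(one, 4.0, 0.01, schedule)
            deposit_bias(two, np.array([4.0, 6.0]), 0.01, schedule)
        assert one.integral == pytest.approx(KT * t / 50.0, rel=1e-9)
        assert two.integral == pytest.approx(2 * KT * t / 50.0, rel=1e-9)

    def test_out_of_range_walker_deposits_nothing(self, caplog):
        grid = BiasGrid(0.0, 10.0, 1.0)
        with caplog.at_level(logging.WARNING, logger="unspool.abmd"):
            deposit_bias(grid, 12.0, 0.01, FloodingSchedule(tau=10.0))
        assert grid.integral == 0.0
        assert "outside bias range" in caplog.text

    def test_edge_deposits_conserve_weight(self):
        # kernel truncated at the grid boundary is renormalized there
        grid = BiasGrid(0.0, 10.0, 1.0)
        deposit_bias(grid, 0.0, 0.01, FloodingSchedule(tau=10.0))
        assert grid.integral == pytest.approx(KT * 0.01 / 10.0, rel=1e-9)

    @given(st.lists(st.floats(0.5, 9.5), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_conservation_for_arbitrary_in_range_positions(self, positions):
        grid = BiasGrid(0.0, 10.0, 0.5)
        schedule = FloodingSchedule(tau=25.0)
        deposit_bias(grid, np.asarray(positions), 0.02, schedule)
        expected = len(positions) * KT * 0.02 / 25.0
        assert grid.integral == pytest.approx(expected, rel=1e-9)


class TestWalls:
    def test_zero_between_walls(self):
        d = np.linspace(25.0, 195.0, 11)
        assert np.all(wall_energy(d, 25.0, 195.0) == 0)

    def test_quadratic_beyond_wall(self):
        assert wall_energy(24.0, 25.0, 195.0, k_wall=10.0) == pytest.approx(10.0)

    @given(st.floats(0.01, 20.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_excursions(self, excess):
        lo, hi = 25.0, 195.0
        assert wall_energy(lo - excess, lo, hi) == pytest.approx(
            wall_energy(hi + excess, lo, hi)
        )

    def test_invalid_wall_order(self):
        with pytest.raises(ValueError):
            wall_energy(0.0, 5.0, 1.0)


@pytest.fixture(scope="module")
def short_run():
    spec = PotentialSpec("harmonic", {"k": 0.5, "center": 5.0}, (0.0, 10.0))
    return run_multiwalker(
        ScalarSystem(spec),
        n_walkers=4,
        bias_range=(0.0, 10.0),
        walls=(1.0, 9.0),
        schedule=FloodingSchedule(tau=20.0),
        total_time=100.0,
        seed=13,
        resolution=0.5,
        dt=0.02,
        gamma=1.0,
        record_interval=10,
        snapshot_interval=10.0,
        store_states=False,
    )


class TestMultiWalker:
    def test_deposit_conservation_identity(self, short_run):
        expected = KT / 20.0 * short_run.residence_time
        assert short_run.bias.integral == pytest.approx(expected, rel=1e-6)

    def test_bias_is_monotone_in_time(self, short_run):
        diffs = np.diff(short_run.snapshots, axis=0)
        assert np.all(diffs >= -1e-12)

    def test_deterministic_given_seed(self):
        spec = PotentialSpec("harmonic", {"k": 0.5, "center": 5.0}, (0.0, 10.0))
        kwargs = dict(
            n_walkers=3, bias_range=(0.0, 10.0), walls=(1.0, 9.0),
            schedule=FloodingSchedule(tau=20.0), total_time=20.0, seed=7,
            resolution=0.5, dt=0.02, gamma=1.0, record_interval=10,
            store_states=False,
        )
        a = run_multiwalker(ScalarSystem(spec), **kwargs)
        b = run_multiwalker(ScalarSystem(spec), **kwargs)
        assert np.array_equal(a.bias.values, b.bias.values)
        assert np.array_equal(a.trajectories[2].d, b.trajectories[2].d)

    def test_infinite_tau_reduces_to_unbiased(self):
        spec = PotentialSpec("harmonic", {"k": 0.5, "center": 5.0}, (0.0, 10.0))
        res = run_multiwalker(
            ScalarSystem(spec), n_walkers=1, bias_range=(0.0, 10.0),
            walls=(1.0, 9.0), schedule=FloodingSchedule(tau=1e12),
            total_time=20.0, seed=3, resolution=0.5, dt=0.02, gamma=1.0,
            record_interval=10, store_states=False,
        )
        assert res.bias.values.max() < 1e-6


class TestDroppedEnergy:
    def test_constant_bias_gives_zero_drops(self):
        snaps = np.tile(np.linspace(0, 3, 11), (4, 1))
        assert np.all(dropped_energy_profile(snaps) == 0)

    def test_single_deposit_column_conserves_weight(self):
        grid = BiasGrid(0.0, 10.0, 0.5)
        before = grid.values.copy()
        deposit_bias(grid, 5.0, 0.1, FloodingSchedule(tau=10.0))
        dropped = dropped_energy_profile(np.stack([before, grid.values]))
        assert dropped[:, 0].sum() * 0.5 == pytest.approx(KT * 0.1 / 10.0, rel=1e-9)

    def test_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            dropped_energy_profile(np.zeros((1, 5)))


class TestFloodingConvergence:
    """Long-run behaviour on the double-well benchmark (shared fixture)."""

    def test_walkers_cover_the_whole_range(self, abmd_bench):
        ds = np.concatenate([t.d for t in abmd_bench.result.trajectories])
        nodes = abmd_bench.nodes
        inner = (nodes >= 2.0) & (nodes <= 8.0)
        counts, _ = np.histogram(ds, bins=np.r_[nodes - 0.125, nodes[-1] + 0.125])
        assert np.all(counts[inner] > 0)

    def test_negated_bias_tracks_free_energy(self, abmd_bench):
        assert abmd_bench.rmsd < 0.3

    def test_residual_landscape_is_flat(self, abmd_bench):
        # range of V + U over the well-to-well region, vs the 3 kcal barrier
        assert abmd_bench.flatness_range <= 0.2 * abmd_bench.barrier

    def test_late_deposition_is_uniform(self, abmd_bench):
        assert abmd_bench.uniformity < 0.2

    def test_uniformity_improves_during_the_run(self, abmd_bench):
        dropped = dropped_energy_profile(abmd_bench.result.snapshots)
        nodes = abmd_bench.nodes
        inner = (nodes >= 2.5) & (nodes <= 7.5)
        metrics = [
            uniformity_metric(dropped[:, : j + 1], node_mask=inner)
            for j in range(dropped.shape[1])
        ]
        assert metrics[-1] < metrics[0]
        assert metrics[-1] <= min(metrics[:3])

    def test_deposit_conservation_on_benchmark(self, abmd_bench):
        assert abmd_bench.conservation_rel_error < 1e-6
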