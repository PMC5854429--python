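"""Synthetic systems: analytic oracles, integrator statistics, mimic model."""

import numpy as np
import pytest
from scipy import stats

from unspool.constants import kbt
from unspool.toy_systems import (
    PotentialSpec,
    ScalarSystem,
    SpoolMimic,
    SpoolMimicSpec,
    SystemState,
    analytic_free_energy,
    boltzmann_density,
    count_distribution,
    free_energy_vs_count,
    langevin_step,
    reduced_count_distribution,
    simulate_trajectory,
)

KT = kbt(300.0)


class TestAnalyticPotentials:
    def test_harmonic_minimum_anchored_and_symmetric(self):
        spec = PotentialSpec("harmonic", {"k": 1.0}, (-5.0, 5.0))
        prof = analytic_free_energy(spec, np.array([-2.0, 0.0, 2.0]))
        assert prof.f[1] == pytest.approx(0.0, abs=1e-12)
        assert prof.f[0] == pytest.approx(prof.f[2], rel=1e-12)
        assert prof.f[0] == pytest.approx(4.0)  # k x^2 convention

    def test_double_well_barrier_matches_parameter(self):
        spec = PotentialSpec(
            "double_well", {"barrier": 3.0, "half_separation": 2.0, "center": 5.0},
            (0.0, 10.0),
        )
        grid = np.linspace(2.0, 8.0, 241)
        prof = analytic_free_energy(spec, grid)
        inner = (grid > 3.0) & (grid < 7.0)
        assert np.nanmax(prof.f[inner]) == pytest.approx(3.0, abs=1e-6)

    def test_grid_outside_domain_rejected(self):
        spec = PotentialSpec("harmonic", {"k": 1.0}, (0.0, 4.0))
        with pytest.raises(ValueError, match="domain"):
            analytic_free_energy(spec, np.array([-1.0, 2.0]))

    def test_tabulated_tracks_tables_and_forces_are_gradients(self):
        x = np.linspace(0, 10, 41)
        spec = PotentialSpec("tabulated", {"x": x, "v": np.sin(x)}, (0.0, 10.0))
        q = np.linspace(0.5, 9.5, 50)
        h = 1e-6
        num = -(spec.energy(q + h) - spec.energy(q - h)) / (2 * h)
        assert np.allclose(spec.force(q), num, atol=1e-5)

    @pytest.mark.parametrize("kind,params", [
        ("harmonic", {"k": -1.0}),
        ("double_well", {"barrier": 0.0, "half_separation": 1.0}),
        ("unknown", {}),
    ])
    def test_invalid_specs_rejected(self, kind, params):
        with pytest.raises(ValueError):
            PotentialSpec(kind, params, (0.0, 1.0))


class TestLangevin:
    def test_ballistic_limit_conserves_energy(self, rng):
        state = SystemState(np.array([0.0]), np.array([1.3]))
        for _ in range(100):
            state = langevin_step(state, lambda x: np.zeros_like(x), 0.01, 0.0, 300.0, rng)
        assert state.velocities[0] == pytest.approx(1.3, rel=1e-12)
        assert state.positions[0] == pytest.approx(1.3, rel=1e-9)

    def test_fixed_seed_reproducible(self):
        spec = PotentialSpec("harmonic", {"k": 1.0}, (-10.0, 10.0))
        system = ScalarSystem(spec)
        t1 = simulate_trajectory(system, n_steps=500, record_interval=10, seed=5,
                                 dt=0.01, gamma=1.0, temperature=300.0)
        t2 = simulate_trajectory(system, n_steps=500, record_interval=10, seed=5,
                                 dt=0.01, gamma=1.0, temperature=300.0)
        assert np.array_equal(t1.d, t2.d)

    def test_harmonic_variance_matches_boltzmann(self):
        # <x^2> = kBT / (2k) for V = k x^2
        k = 1.0
        spec = PotentialSpec("harmonic", {"k": k}, (-10.0, 10.0))
        system = ScalarSystem(spec)
        traj = simulate_trajectory(system, n_steps=200000, record_interval=10, seed=3,
                                   dt=0.02, gamma=1.0, temperature=300.0)
        x2 = traj.d**2
        blocks = x2.reshape(10, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(x2.mean() - KT / (2 * k)) < 3 * se + 1e-4

    def test_unbiased_histogram_matches_boltzmann_density(self):
        spec = PotentialSpec(
            "double_well", {"barrier": 1.0, "half_separation": 1.5, "center": 5.0},
            (0.0, 10.0),
        )
        system = ScalarSystem(spec)
        traj = simulate_trajectory(system, n_steps=1000000, record_interval=50, seed=9,
                                   dt=0.02, gamma=0.5, temperature=300.0)
        grid = np.linspace(0, 10, 2001)
        dens = boltzmann_density(spec, grid)
        cdf = np.cumsum(dens) * (grid[1] - grid[0])
        cdf /= cdf[-1]
        ks = stats.kstest(traj.d, lambda q: np.interp(q, grid, cdf)).statistic
        assert ks < 0.05

    def test_invalid_step_arguments(self, rng):
        state = SystemState(np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            langevin_step(state, lambda x: -x, -0.01, 1.0, 300.0, rng)
        with pytest.raises(ValueError):
            langevin_step(state, lambda x: -x, 0.01, 1.0, -5.0, rng)

    def test_nonfinite_force_names_offender(self, rng):
        state = SystemState(np.array([0.0, 1.0]), np.zeros(2))

        def bad(x):
            f = -x
            f[..., 1] = np.nan
            return f

        with pytest.raises(FloatingPointError, match="dof"):
            langevin_step(state, bad, 0.01, 1.0, 300.0, rng)

    def test_record_interval_must_divide(self):
        system = ScalarSystem(PotentialSpec("harmonic", {"k": 1.0}, (-5.0, 5.0)))
        with pytest.raises(ValueError):
            simulate_trajectory(system, n_steps=1001, record_interval=10, seed=0)

    def test_sample_count_arithmetic(self):
        system = ScalarSystem(PotentialSpec("harmonic", {"k": 1.0}, (-5.0, 5.0)))
        traj = simulate_trajectory(system, n_steps=1000, record_interval=10, seed=0)
        assert traj.n_samples == 100


class TestSpoolMimic:
    def test_mirror_symmetry(self, rng):
        mimic = SpoolMimic(SpoolMimicSpec())
        x = rng.uniform(0, 8, size=(5, 2, 10))
        swapped = x[:, ::-1, :]
        assert np.allclose(mimic.energy(x), mimic.energy(swapped))
        assert np.allclose(mimic.reaction_coordinate(x), mimic.reaction_coordinate(swapped))

    def test_forces_are_exact_gradients(self, rng):
        mimic = SpoolMimic(SpoolMimicSpec())
        x = rng.uniform(0.2, 7.8, size=(2, 10))
        f = mimic.force(x)
        h = 1e-6
        for a in range(2):
            for j in range(10):
                xp = x.copy(); xp[a, j] += h
                xm = x.copy(); xm[a, j] -= h
                num = -(mimic.energy(xp) - mimic.energy(xm)) / (2 * h)
                assert f[a, j] == pytest.approx(num, abs=2e-4)

    def test_fully_wrapped_energy_is_total_binding_energy(self):
        spec = SpoolMimicSpec()
        mimic = SpoolMimic(spec)
        x = np.zeros((2, spec.n_beads))
        assert mimic.energy(x) == pytest.approx(-spec.total_binding_energy)
        assert spec.total_binding_energy == pytest.approx(8.0)

    def test_counts_contiguous_vs_any(self):
        mimic = SpoolMimic(SpoolMimicSpec())
        x = np.zeros((2, 10))
        x[0, 0] = 6.0  # outermost unwrapped
        x[0, 2] = 6.0  # isolated inner bead
        assert mimic.counts_any(x)[0] == 2
        assert mimic.counts_contiguous(x)[0] == 1
        assert mimic.counts_any(x)[1] == 0

    def test_reaction_coordinate_deterministic_and_nonnegative(self, rng):
        mimic = SpoolMimic(SpoolMimicSpec())
        x = rng.uniform(0, 8, size=(4, 2, 10))
        d = mimic.reaction_coordinate(x)
        assert np.all(d >= 0)
        assert np.allclose(d, mimic.spec.base_extension + x.sum(axis=(1, 2)))

    def test_shrink_arms_moves_sites_outward(self):
        spec = SpoolMimicSpec()
        small = spec.shrink_arms(3)
        assert small.n_beads == 7
        # sites that sat on beads 0 disappear; the rest shift by 3
        assert tuple(small.resolved_site_beads) == (0, 3, 6)
        assert small.n_sites == 3

    def test_spec_roundtrip(self):
        spec = SpoolMimicSpec(site_energies=(0.5, 1.0, 1.5, 2.0), pinned_arms=(1,))
        assert SpoolMimicSpec.from_dict(spec.to_dict()) == spec

    def test_pinned_arm_never_moves(self):
        spec = SpoolMimicSpec(pinned_arms=(1,))
        mimic = SpoolMimic(spec)
        traj = simulate_trajectory(mimic, n_steps=2000, record_interval=100, seed=4,
                                   store_states=True)
        assert np.all(traj.aux["unwrapped_end2"] == 0)
        assert np.allclose(traj.states[:, 1, :], traj.states[0, 1, :])

    def test_unbound_arms_detach_freely(self):
        # with all site energies zero nothing holds the arms wrapped
        spec0 = SpoolMimicSpec(site_energies=(0.0,) * 4)
        traj = simulate_trajectory(SpoolMimic(spec0), n_steps=60000, record_interval=60,
                                   seed=6, gamma=0.5)
        total = traj.aux["unwrapped_end1"] + traj.aux["unwrapped_end2"]
        assert total[len(total) // 2:].mean() > 3.0

    def test_bound_arms_unwrap_more_at_higher_temperature(self):
        # exact check: thermal unbinding beats the site energies as T grows
        means = []
        for temp in (200.0, 600.0):
            counts, p_total, _ = count_distribution(SpoolMimicSpec(), temperature=temp)
            means.append(float((counts * p_total).sum()))
        assert means[1] > means[0]


class TestCountOracles:
    def test_exact_and_reduced_models_agree_on_step_pattern(self):
        spec = SpoolMimicSpec()
        kt = kbt(spec.temperature)
        _, _, pa = count_distribution(spec)
        _, _, pa_red = reduced_count_distribution(spec)
        f = -kt * np.log(pa); f -= f[0]
        f_red = -kt * np.log(pa_red); f_red -= f_red[0]
        # same end point (unique end states) and site steps within the
        # gating/shoulder corrections
        assert f[-1] == pytest.approx(f_red[-1], abs=0.35)
        sites = np.sort(spec.resolved_site_beads) + 1
        for c in sites:
            assert f[c] - f[c - 1] == pytest.approx(1.0, abs=0.1)

    def test_enumeration_matches_long_run_sampling(self):
        # one bead per arm: the occupancy model is exactly samplable
        spec = SpoolMimicSpec(n_beads=1, n_sites=1, site_energies=(1.0,),
                              site_beads=(0,))
        counts, p_total, p_arm = count_distribution(spec)
        traj = simulate_trajectory(SpoolMimic(spec), n_steps=120000,
                                   record_interval=20, seed=8)
        occ = (traj.aux["unwrapped_end1"] > 0).astype(float)
        blocks = occ.reshape(12, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(occ.mean() - p_arm[1]) < 3 * se + 5e-3

    def test_pinned_arm_distribution_collapses(self):
        spec = SpoolMimicSpec(pinned_arms=(1,))
        counts, p_total, p_arm = count_distribution(spec)
        free_counts, free_total, _ = count_distribution(SpoolMimicSpec())
        assert np.allclose(p_total[: len(p_arm)], p_arm)
        assert p_total[len(p_arm):].sum() == pytest.approx(0.0)

    def test_profile_units_and_anchor(self):
        prof = free_energy_vs_count(SpoolMimicSpec())
        assert np.nanmin(prof.f) == pytest.approx(0.0)
        assert prof.p.sum() == pytest.approx(1.0, abs=1e-12)


class TestTrajectoryIO:
    def test_csv_roundtrip_with_sidecar(self, tmp_path):
        mimic = SpoolMimic(SpoolMimicSpec())
        traj = simulate_trajectory(mimic, n_steps=200, record_interval=20, seed=2)
        path = tmp_path / "traj.csv"
        traj.to_csv(path, sidecar={"seed": 2})
        import pandas as pd, json

        df = pd.read_csv(path)
        for col in ("time_ps", "d_A", "unwrapped_end1", "unwrapped_end2", "energy_kcal_mol"):
            assert col in df.columns
        assert len(df) == traj.n_samples
        assert json.loads(path.with_suffix(".json").read_text())["seed"] == 2
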