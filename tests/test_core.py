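import numpy as np
import pytest

from markspread import (
    ConfigurationError,
    LatticeState,
    NeighborSystem,
    ParticleSystem,
    RDParams,
    demethylation_sweep,
    methylation_sweep,
    run_rd_simulation,
)
from markspread.state import SPECIES_C, STATE_M


class TestRDParamsValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_nucleosomes": 60}, "odd"),
            ({"n_nucleosomes": 61, "radius": 10.0}, "radius"),
            ({"p_m": 1.5}, "p_m"),
            ({"p_rd": -0.1}, "p_rd"),
            ({"burn_in": 200_000}, "burn_in"),
            ({"sample_interval": 0}, "sample_interval"),
            ({"d_prox": 0.0}, "d_prox"),
            ({"d_tilde": -1e-4}, "d_tilde"),
        ],
    )
    def test_invariant_violations_named(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            RDParams(**kwargs).validate()

    def test_defaults_are_valid(self):
        RDParams().validate()


class TestRunTrivialLimits:
    def test_no_catalyst_no_spreading(self):
        """No enzymes, no RNA production: P(M) is 1 at the nucleation point
        and 0 everywhere else."""
        params = RDParams(
            n_nucleosomes=11,
            radius=8.0,
            n_enzymes=0,
            p_rp=0.0,
            n_steps=2000,
            burn_in=500,
            sample_interval=50,
            seed=1,
        )
        result = run_rd_simulation(params)
        expected = np.zeros(11)
        expected[5] = 1.0
        assert np.array_equal(result.profile.p, expected)
        assert len(result.particles) == 0

    def test_absorbing_m_states_fill_lattice(self):
        """P_dm = 0, P_m = 1: with a sustained complex supply every site
        reachable from the nucleation point ends modified."""
        params = RDParams(
            n_nucleosomes=11,
            radius=8.0,
            n_enzymes=30,
            p_rd=1e-3,
            p_cd=0.0,
            p_dm=0.0,
            p_rp=0.02,
            n_steps=150_000,
            burn_in=140_000,
            sample_interval=500,
            seed=2,
        )
        result = run_rd_simulation(params)
        assert np.all(result.profile.p == 1.0)

    def test_all_u_lattice_absorbing_without_writer_pathway(self):
        """P_w = 0 and no nucleation point: no mark can ever appear."""
        params = RDParams(
            n_nucleosomes=11,
            radius=8.0,
            n_enzymes=50,
            nucleation_enabled=False,
            p_w=0.0,
            n_steps=50_000,
            burn_in=1000,
            sample_interval=100,
            seed=3,
        )
        result = run_rd_simulation(params)
        assert np.all(result.profile.p == 0.0)
        assert np.all(result.lattice_samples == 0)


class TestRunInvariants:
    def test_enzyme_conservation_and_confinement(self, small_rd_params):
        result = run_rd_simulation(small_rd_params)
        counts = result.species_counts
        assert np.all(counts[:, 0] + counts[:, 2] == small_rd_params.n_enzymes)
        assert result.metadata["enzyme_conservation_ok"]
        assert result.max_particle_radius <= small_rd_params.radius + 1e-9
        pos = result.particles.positions
        assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= small_rd_params.radius + 1e-9)

    def test_nucleation_point_always_modified(self, small_rd_params):
        result = run_rd_simulation(small_rd_params)
        center = (small_rd_params.n_nucleosomes - 1) // 2
        assert np.all(result.lattice_samples[:, center] == 1)
        assert result.profile.p[center] == 1.0

    def test_determinism_bit_identical(self, small_rd_params):
        a = run_rd_simulation(small_rd_params)
        b = run_rd_simulation(small_rd_params)
        assert np.array_equal(a.lattice_samples, b.lattice_samples)
        assert np.array_equal(a.species_counts, b.species_counts)
        assert np.array_equal(a.particles.positions, b.particles.positions)
        assert np.array_equal(a.cprox, b.cprox)

    def test_different_seed_different_trajectory(self, small_rd_params):
        a = run_rd_simulation(small_rd_params)
        b = run_rd_simulation(small_rd_params.replace(seed=8))
        assert not np.array_equal(a.particles.positions, b.particles.positions)

    def test_ensemble_profile_mirror_symmetric(self):
        """P(M at +i) approaches P(M at -i) as the ensemble grows."""
        params = RDParams(
            n_nucleosomes=21,
            radius=12.0,
            n_enzymes=100,
            p_cd=1e-4,
            n_steps=40_000,
            burn_in=10_000,
            sample_interval=150,
            seed=0,
        )
        profs = [
            run_rd_simulation(params.replace(seed=s)).profile.p for s in range(6)
        ]
        mean = np.mean(profs, axis=0)
        asym = np.abs(mean - mean[::-1])
        assert asym.max() < 0.1

    def test_rna_cap_overflow_warns(self):
        params = RDParams(
            n_nucleosomes=5,
            radius=4.0,
            n_enzymes=0,
            p_rp=1.0,
            p_rd=0.0,
            rna_cap=5,
            n_steps=200,
            burn_in=100,
            sample_interval=10,
            seed=4,
        )
        with pytest.warns(RuntimeWarning, match="rna_cap"):
            result = run_rd_simulation(params)
        assert result.species_counts[-1, 1] == 5


class TestEngineAgainstModularOperations:
    def test_flooded_lattice_matches_synchronous_chain(self, rng):
        """When complexes saturate the whole disc, the engine's lattice
        dynamics reduce to the synchronous methylation/demethylation chain
        built from the modular sweep operations; per-site P(M) must agree.
        """
        p_m, p_dm = 0.4, 0.25
        n_sites = 7
        params = RDParams(
            n_nucleosomes=n_sites,
            radius=5.0,
            n_enzymes=10,
            d_prox=20.0,  # every site sees every complex, every R every E
            p_rp=1.0,
            p_rd=0.05,
            p_cd=0.0,
            p_m=p_m,
            p_dm=p_dm,
            n_steps=41_000,
            burn_in=1000,
            sample_interval=10,
            seed=5,
        )
        engine_p = run_rd_simulation(params).profile.p

        # independent reference: iterate the modular sweeps directly with a
        # permanently proximal complex
        lat = LatticeState.linear(n_sites, nucleation_enabled=True)
        nbrs = NeighborSystem.linear(n_sites)
        c = ParticleSystem(np.zeros((1, 2)), np.array([SPECIES_C], dtype=np.int8))
        acc = np.zeros(n_sites)
        n_samp = 0
        for step in range(1, 41_001):
            lat = methylation_sweep(lat, c, nbrs, 20.0, 0.0, p_m, rng)
            lat = demethylation_sweep(lat, p_dm, True, rng)
            lat.states[lat.np_index] = STATE_M
            if step > 1000 and step % 10 == 0:
                acc += lat.states
                n_samp += 1
        ref_p = acc / n_samp
        # both are Monte-Carlo estimates over >= 4000 near-independent
        # samples; binomial SE per site is ~0.008
        assert np.abs(engine_p - ref_p).max() < 0.05


class TestPolymerEquivalence:
    def test_straight_rod_reduces_to_linear_lattice(self, small_rd_params):
        from markspread import PolymerConfig

        n = small_rd_params.n_nucleosomes
        rod = PolymerConfig(
            np.column_stack(
                [np.arange(n, dtype=float) - (n - 1) // 2, np.zeros(n)]
            ),
            "SAW",
            1.5,
        )
        linear = run_rd_simulation(small_rd_params)
        polymer = run_rd_simulation(small_rd_params, polymer=rod)
        assert np.array_equal(linear.lattice_samples, polymer.lattice_samples)
        assert np.array_equal(linear.particles.positions, polymer.particles.positions)

    def test_bead_count_mismatch_rejected(self, small_rd_params, rng):
        from markspread import generate_rw_2d

        config = generate_rw_2d(11, rng)
        with pytest.raises(ConfigurationError, match="beads"):
            run_rd_simulation(small_rd_params, polymer=config)

    def test_frozen_configuration_not_mutated(self, rng):
        from markspread import generate_saw_2d

        config = generate_saw_2d(11, rng)
        before = config.coords.copy()
        params = RDParams(
            n_nucleosomes=11,
            radius=float(np.hypot(*config.coords.T).max() + 3),
            n_enzymes=20,
            n_steps=3000,
            burn_in=1000,
            sample_interval=100,
            seed=6,
        )
        run_rd_simulation(params, polymer=config)
        assert np.array_equal(config.coords, before)
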