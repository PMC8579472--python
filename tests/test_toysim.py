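"""Toy-system energies, the alchemical coupling, and the Metropolis sampler."""

import math

import numpy as np
import pytest

from fegrad.alchemy import SamplerConfig, block_average
from fegrad.forcefield import ParameterSpace
from fegrad.toysim import (KB, CoupledPotential, Species, ThermoState,
                           ToyEngine, ToySystem, build_solvation_box,
                           coupled_energy, metropolis_sample, sample_harmonic,
                           total_energy)


class TestPairEnergies:
    def test_lj_zero_crossing_at_sigma(self, two_particle_system):
        assert total_energy(two_particle_system) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self, two_particle_system):
        r_min = 2 ** (1 / 6) * 0.4
        sys_ = two_particle_system.with_positions(
            np.array([[1.0, 1.0, 1.0], [1.0 + r_min, 1.0, 1.0]]))
        assert total_energy(sys_) == pytest.approx(-1.0)

    def test_noninteracting_system_has_zero_energy(self, two_particle_system):
        sys_ = two_particle_system.with_site_params(
            epsilon=np.zeros(2), charge=np.zeros(2))
        assert total_energy(sys_) == 0.0

    def test_overlapping_sites_raise(self, two_particle_system):
        sys_ = two_particle_system.with_positions(
            np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + 1e-9]]))
        with pytest.raises(ValueError, match="overlap"):
            total_energy(sys_)

    def test_translation_invariance(self, tiny_lj_box):
        """Shifting all sites by a lattice-commensurate vector leaves the
        energy unchanged (periodic wrap + minimum image)."""
        sys_ = tiny_lj_box
        e0 = total_energy(sys_)
        shift = np.array([sys_.L, -2 * sys_.L, sys_.L])
        e1 = total_energy(sys_.with_positions(sys_.positions + shift))
        assert abs(e1 - e0) < 1e-9
        # non-commensurate shifts also preserve pair energies, but move the
        # solute off its tether minimum; compare with tether disabled
        import dataclasses
        free = dataclasses.replace(sys_, tether_k=0.0)
        e0 = total_energy(free)
        rng = np.random.default_rng(1)
        e1 = total_energy(
            free.with_positions(free.positions + rng.uniform(-1, 1, 3)))
        assert abs(e1 - e0) < 1e-9

    def test_box_must_exceed_twice_cutoff(self, two_particle_system):
        import dataclasses
        with pytest.raises(ValueError, match="twice the cutoff"):
            dataclasses.replace(two_particle_system, L=2.0, r_c=1.4)


class TestCoupledPotential:
    @pytest.mark.parametrize("mode", ["linear", "softcore"])
    def test_endpoints_match_u0_and_u1(self, tiny_lj_box, mode):
        cp = CoupledPotential(mode=mode, stage="combined")
        eng = ToyEngine(tiny_lj_box, cp)
        pos = tiny_lj_box.positions[None]
        u0 = eng.u0_batch(pos)[0]
        u1 = u0 + eng.delta_u_batch(pos)[0]
        assert coupled_energy(tiny_lj_box, cp, 0.0) == pytest.approx(u0, rel=1e-12)
        assert coupled_energy(tiny_lj_box, cp, 1.0) == pytest.approx(u1, rel=1e-12)

    def test_linear_midpoint(self, tiny_lj_box):
        cp = CoupledPotential(mode="linear")
        u0 = coupled_energy(tiny_lj_box, cp, 0.0)
        u1 = coupled_energy(tiny_lj_box, cp, 1.0)
        assert coupled_energy(tiny_lj_box, cp, 0.5) == pytest.approx(
            (u0 + u1) / 2, rel=1e-12)

    def test_alpha_outside_unit_interval_rejected(self, tiny_lj_box):
        cp = CoupledPotential()
        with pytest.raises(ValueError, match="alpha"):
            coupled_energy(tiny_lj_box, cp, 1.5)

    def test_linear_dudalpha_equals_instantaneous_gap(self, tiny_lj_box):
        """The premise of gradient fitting: dU/dalpha = U1 - U0 = dU holds
        exactly for every configuration on the linear path."""
        cp = CoupledPotential(mode="linear", stage="combined")
        eng = ToyEngine(tiny_lj_box, cp)
        rng = np.random.default_rng(0)
        pos = (tiny_lj_box.positions[None]
               + rng.normal(0, 0.01, (6,) + tiny_lj_box.positions.shape))
        du = eng.delta_u_batch(pos)
        for a in (0.0, 0.3, 1.0):
            assert np.allclose(eng.dudalpha_batch(pos, a), du, rtol=1e-12)
            num = (eng.e_alpha_batch(pos, a + 1e-6)
                   - eng.e_alpha_batch(pos, max(a - 1e-6, 0.0)))
            h = 1e-6 + (a - max(a - 1e-6, 0.0))
            assert np.allclose(num / h, du, rtol=1e-5, atol=1e-5)

    def test_softcore_dudalpha_matches_numerical_derivative(self, tiny_lj_box):
        cp = CoupledPotential(mode="softcore", stage="vdw")
        eng = ToyEngine(tiny_lj_box, cp)
        pos = tiny_lj_box.positions[None]
        for a in (0.2, 0.5, 0.8):
            num = (eng.e_alpha_batch(pos, a + 1e-6)
                   - eng.e_alpha_batch(pos, a - 1e-6)) / 2e-6
            assert eng.dudalpha_batch(pos, a)[0] == pytest.approx(
                num[0], rel=1e-5)


class TestMetropolis:
    def test_ideal_gas_accepts_every_move(self, state):
        solute = Species("solute", 0.4, 0.0, 0.0, role="solute")
        solvent = Species("solvent", 0.4, 0.0, 0.0)
        sys_ = build_solvation_box(solute, {solvent: 15}, L=2.2, r_c=0.9,
                                   seed=1, tether_k=0.0)
        cfg = SamplerConfig(seed=9, n_equil=200, n_steps=2000, save_every=20)
        snaps = metropolis_sample(sys_, CoupledPotential(), 0.5, state, cfg)
        assert snaps.acceptance_ratio == 1.0
        assert np.allclose(snaps.delta_u, 0.0)

    def test_same_seed_reproduces_snapshots_bitwise(self, tiny_lj_box, state,
                                                    fast_sampler):
        cp = CoupledPotential(mode="linear", stage="vdw")
        s1 = metropolis_sample(tiny_lj_box, cp, 0.7, state, fast_sampler)
        s2 = metropolis_sample(tiny_lj_box, cp, 0.7, state, fast_sampler)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.delta_u, s2.delta_u)

    def test_delta_u_cache_matches_recomputation(self, tiny_lj_box, state,
                                                 fast_sampler):
        cp = CoupledPotential(mode="linear", stage="vdw")
        snaps = metropolis_sample(tiny_lj_box, cp, 0.9, state, fast_sampler)
        assert np.allclose(snaps.delta_u, snaps.recompute_delta_u(),
                           atol=1e-9)

    def test_harmonic_second_moment(self):
        """1-D harmonic test hook: <x^2> = kT/kappa within 3 SE."""
        kappa, kT = 2.0, 1.0
        cfg = SamplerConfig(seed=4, n_equil=2000, n_steps=60000,
                            save_every=10, max_displacement=1.2)
        snaps = sample_harmonic(kappa, kappa, 0.0, 1.0 / kT, cfg)
        mean, se, _ = block_average(snaps.positions ** 2)
        assert abs(mean - kT / kappa) < 3 * se

    def test_boltzmann_state_frequencies(self, state):
        """Detailed-balance smoke test: occupation of distance shells for a
        2-particle box matches brute-force quadrature of the Boltzmann
        weight over the relative coordinate."""
        a = Species("a", 0.35, 1.5, 0.0, role="solute")
        b = Species("b", 0.35, 1.5, 0.0)
        L, rc = 2.2, 0.9
        sys_ = ToySystem(L=L, r_c=rc, positions=np.array(
            [[1.1, 1.1, 1.1], [1.6, 1.1, 1.1]]),
            species={"a": a, "b": b}, labels=("a", "b"), tether_k=0.0)
        beta = state.beta

        # brute-force oracle: integrate exp(-beta U(r)) over the relative
        # displacement on a dense grid (uniform base measure in the box)
        n = 80
        g = (np.arange(n) + 0.5) / n * L - L / 2
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        sij, eij = 0.35, 1.5
        u = np.zeros_like(r)
        inside = (r < rc) & (r > 1e-9)
        sr6 = (sij / r[inside]) ** 6
        u[inside] = 4 * eij * (sr6 ** 2 - sr6)
        w = np.exp(-beta * np.clip(u, -50 / beta, 50 / beta))
        r_split = 0.45
        p_near_exact = float(w[r < r_split].sum() / w.sum())

        cfg = SamplerConfig(seed=12, n_equil=5000, n_steps=400000,
                            save_every=40, max_displacement=0.4)
        snaps = metropolis_sample(sys_, CoupledPotential(), 1.0, state, cfg)
        d = snaps.positions[:, 0, :] - snaps.positions[:, 1, :]
        d -= L * np.round(d / L)
        dist = np.linalg.norm(d, axis=1)
        indicator = (dist < r_split).astype(float)
        p_near, se, _ = block_average(indicator, n_blocks=20)
        assert abs(p_near - p_near_exact) < 3 * max(se, 1e-4)

    def test_run_length_validation(self):
        with pytest.raises(ValueError, match="n_steps"):
            SamplerConfig(seed=0, n_steps=10, save_every=20)


class TestSnapshotArchive:
    def test_round_trip_preserves_configurations(self, tiny_lj_box, state,
                                                 fast_sampler, tmp_path):
        from fegrad.toysim import load_snapshots, save_snapshots
        cp = CoupledPotential(mode="linear", stage="vdw")
        snaps = metropolis_sample(tiny_lj_box, cp, 0.8, state, fast_sampler)
        path = tmp_path / "snaps.txt"
        save_snapshots(path, snaps)
        back = load_snapshots(path)
        assert np.array_equal(back.positions, snaps.positions)
        assert np.array_equal(back.delta_u, snaps.delta_u)
        assert back.alpha == snaps.alpha

    def test_version_header_enforced(self, tmp_path):
        from fegrad.toysim import load_snapshots
        bad = tmp_path / "bad.txt"
        bad.write_text("no header\n")
        with pytest.raises(ValueError, match="header"):
            load_snapshots(bad)


class TestConstantPressure:
    def test_ideal_gas_volume_matches_equation_of_state(self, state):
        """For an ideal gas the NPT volume average is (N+1) kT / P."""
        import dataclasses
        from fegrad.toysim import BAR_NM3, metropolis_sample_npt
        solute = Species("solute", 0.4, 0.0, 0.0, role="solute")
        solvent = Species("solvent", 0.4, 0.0, 0.0)
        sys_ = build_solvation_box(solute, {solvent: 15}, L=2.7, r_c=0.9,
                                   seed=2, tether_k=0.0)
        npt_state = dataclasses.replace(state, P=33.0)
        cfg = SamplerConfig(seed=8, n_equil=20000, n_steps=200000,
                            save_every=100, max_displacement=0.3)
        samples = metropolis_sample_npt(sys_, CoupledPotential(), 1.0,
                                        npt_state, cfg, volume_every=50,
                                        max_dlnv=0.08)
        expected = 16 * KB * npt_state.T / (npt_state.P * BAR_NM3)
        mean, se, _ = block_average(samples.volumes, n_blocks=20)
        assert abs(mean - expected) < 3 * max(se, 0.02 * expected)

    def test_requires_pressure(self, tiny_lj_box, state, fast_sampler):
        from fegrad.toysim import metropolis_sample_npt
        with pytest.raises(ValueError, match="ThermoState.P"):
            metropolis_sample_npt(tiny_lj_box, CoupledPotential(), 1.0,
                                  state, fast_sampler)


class TestThermoState:
    def test_beta_consistent_with_temperature(self):
        st = ThermoState(T=298.15)
        assert st.beta * KB * st.T == pytest.approx(1.0, rel=1e-10)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ThermoState(T=0.0)


class TestParameterBinding:
    def test_apply_parameters_updates_matching_species_only(self, tiny_lj_box):
        space = ParameterSpace.create(
            ("solute.epsilon", "ghost.sigma"), ("epsilon", "sigma"),
            (2.0, 0.4))
        sys_ = tiny_lj_box.apply_parameters(space, np.array([3.0, 0.9]))
        labels = np.array(tiny_lj_box.labels)
        assert np.all(sys_.epsilon[labels == "solute"] == 3.0)
        assert np.array_equal(sys_.sigma, tiny_lj_box.sigma)
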