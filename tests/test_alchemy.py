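"""Free-energy gradient estimation, TI and the fluctuation-formula
parameter derivative, checked against the harmonic-oscillator closed forms:

    <dU>_a = kT (k1 - k0) / (2 k_a),      k_a = (1-a) k0 + a k1
    dF     = (kT / 2) ln(k1 / k0)
    d<dU>_a/dk1 = kT/(2 k_a) - a (k1 - k0) kT / (2 k_a^2)
"""

import numpy as np
import pytest

from fegrad.alchemy import (FitGrid, GradientEstimate, SamplerConfig, Stage,
                            AlphaSchedule, block_average, estimate_dudl,
                            gauss_legendre_grid, param_gradient,
                            read_gradient_table, ti_integrate,
                            vdw_alpha_grid, write_gradient_table)
from fegrad.forcefield import ParameterSpace
from fegrad.toysim import (CoupledPotential, HarmonicEngine, SnapshotSet,
                           ThermoState, harmonic_delta_f_exact,
                           harmonic_dudl_dk1_exact, harmonic_dudl_exact,
                           metropolis_sample, sample_harmonic)

K0, K1 = 1.0, 4.0
BETA1 = ThermoState(T=1.0 / 0.0083144621)  # kT = 1 exactly


def harmonic_snaps(alpha, seed=7, n_steps=60000):
    cfg = SamplerConfig(seed=seed, n_equil=2000, n_steps=n_steps,
                        save_every=10, max_displacement=1.2)
    return sample_harmonic(K0, K1, alpha, 1.0, cfg)


class TestBlockAverage:
    def test_constant_series_has_zero_se(self):
        mean, se, _ = block_average(np.full(100, 3.25))
        assert mean == 3.25
        assert se == 0.0

    def test_se_shrinks_as_inverse_sqrt_n_on_iid_data(self):
        rng = np.random.default_rng(0)
        se_small = np.mean([block_average(rng.normal(size=400))[1]
                            for _ in range(40)])
        se_large = np.mean([block_average(rng.normal(size=6400))[1]
                            for _ in range(40)])
        assert se_large == pytest.approx(se_small / 4, rel=0.15)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.arange(5))


class TestEstimateDudl:
    def test_identical_endpoints_give_zero(self):
        snaps = harmonic_snaps(0.5)
        snaps.delta_u = np.zeros_like(snaps.delta_u)
        snaps.dudalpha = snaps.delta_u
        est = estimate_dudl(snaps)
        assert est.mean == 0.0
        assert est.se == 0.0

    def test_harmonic_mean_within_three_se(self):
        """Pooled over three independent chains so the block-SE estimate
        itself is stable (30 blocks)."""
        ests = [estimate_dudl(harmonic_snaps(0.5, seed=s)) for s in (1, 2, 3)]
        mean = np.mean([e.mean for e in ests])
        se = np.sqrt(np.sum([e.se ** 2 for e in ests])) / 3
        exact = harmonic_dudl_exact(K0, K1, 0.5, 1.0)
        assert exact == pytest.approx(0.6)
        assert abs(mean - exact) < 3 * se

    def test_constant_gap_degenerate_input(self):
        snaps = harmonic_snaps(0.5)
        snaps.delta_u = np.full_like(snaps.delta_u, 2.5)
        snaps.dudalpha = snaps.delta_u
        est = estimate_dudl(snaps)
        assert est.mean == 2.5
        assert est.se == 0.0

    def test_requires_ten_snapshots(self):
        snaps = harmonic_snaps(0.5)
        snaps.delta_u = snaps.delta_u[:5]
        snaps.dudalpha = snaps.delta_u
        with pytest.raises(ValueError):
            estimate_dudl(snaps)


class TestTIIntegrate:
    def test_constant_gradient_integrates_exactly(self):
        ests = [GradientEstimate(a, 2.0, 0.0, 1) for a in (0.0, 0.3, 1.0)]
        assert ti_integrate(ests).delta_f == pytest.approx(2.0)

    def test_all_zero_gradients(self):
        ests = [GradientEstimate(a, 0.0, 0.0, 1) for a in (0.0, 0.5, 1.0)]
        res = ti_integrate(ests)
        assert res.delta_f == 0.0
        assert res.se == 0.0

    def test_harmonic_gauss_legendre_matches_closed_form(self):
        nodes, _ = gauss_legendre_grid(12)
        ests = [GradientEstimate(a, harmonic_dudl_exact(K0, K1, a, 1.0),
                                 0.0, 1) for a in nodes]
        res = ti_integrate(ests, rule="gauss-legendre")
        assert abs(res.delta_f - harmonic_delta_f_exact(K0, K1, 1.0)) < 1e-3

    def test_quadrature_error_decreases_with_refinement(self):
        exact = harmonic_delta_f_exact(K0, K1, 1.0)
        errors = []
        for n in (3, 6, 12):
            grid = np.linspace(0, 1, n)
            ests = [GradientEstimate(a, harmonic_dudl_exact(K0, K1, a, 1.0),
                                     0.0, 1) for a in grid]
            errors.append(abs(ti_integrate(ests).delta_f - exact))
        assert errors[0] > errors[1] > errors[2]

    def test_se_propagates_with_quadrature_weights(self):
        ests = [GradientEstimate(a, 1.0, 0.2, 1) for a in (0.0, 0.5, 1.0)]
        res = ti_integrate(ests)
        expected = np.sqrt(np.sum((res.weights * 0.2) ** 2))
        assert res.se == pytest.approx(expected)

    def test_unsorted_alphas_rejected(self):
        ests = [GradientEstimate(a, 1.0, 0.0, 1) for a in (0.5, 0.2, 1.0)]
        with pytest.raises(ValueError):
            ti_integrate(ests)

    def test_gauss_rule_rejects_mismatched_grid(self):
        ests = [GradientEstimate(a, 1.0, 0.0, 1)
                for a in np.linspace(0.01, 0.99, 4)]
        with pytest.raises(ValueError, match="Gauss-Legendre"):
            ti_integrate(ests, rule="gauss-legendre")

    def test_antisymmetry_under_endpoint_swap(self):
        """Swapping U0 and U1 on the same snapshots negates the gap at the
        mirrored coupling, so every stage dF changes sign exactly."""
        grid = np.linspace(0, 1, 7)
        fwd = [GradientEstimate(a, harmonic_dudl_exact(K0, K1, a, 1.0),
                                0.0, 1) for a in grid]
        rev = [GradientEstimate(1.0 - a, -e.mean, 0.0, 1)
               for a, e in zip(grid, fwd)][::-1]
        assert ti_integrate(rev).delta_f == pytest.approx(
            -ti_integrate(fwd).delta_f, abs=1e-14)


class TestHydrationFreeEnergy:
    def test_three_repeats_reported_with_standard_error(self, tiny_lj_box,
                                                        state):
        from fegrad.alchemy import AlphaSchedule, hydration_free_energy
        sampler = SamplerConfig(seed=0, n_equil=1000, n_steps=8000,
                                save_every=40)
        schedule = AlphaSchedule((Stage(CoupledPotential(mode="softcore",
                                                         stage="vdw"),
                                        np.linspace(0, 1, 4), sampler),))
        res = hydration_free_energy(tiny_lj_box, schedule, state,
                                    n_repeat=3, seed=5)
        assert len(res.replicates) == 3
        assert res.se == max(res.se_repeats, res.se_propagated)
        assert res.se > 0
        assert "decoupling" in res.convention

    def test_noninteracting_solute_has_zero_hfe(self, state):
        from fegrad.alchemy import AlphaSchedule, hydration_free_energy
        from fegrad.toysim import Species, build_solvation_box
        solute = Species("solute", 0.4, 0.0, 0.0, role="solute")
        solvent = Species("solvent", 0.42, 0.8, 0.0)
        sys_ = build_solvation_box(solute, {solvent: 16}, L=2.2, r_c=0.9,
                                   seed=4, tether_k=10.0)
        sampler = SamplerConfig(seed=0, n_equil=500, n_steps=4000,
                                save_every=20)
        schedule = AlphaSchedule((Stage(CoupledPotential(mode="softcore",
                                                         stage="vdw"),
                                        np.linspace(0, 1, 3), sampler),))
        res = hydration_free_energy(sys_, schedule, state, n_repeat=2,
                                    seed=3)
        assert res.total == pytest.approx(0.0, abs=1e-9)


class TestParamGradient:
    def test_harmonic_gradient_matches_closed_form(self):
        space = ParameterSpace.create(("k0", "k1"), ("bond_k", "bond_k"),
                                      (K0, K1), t=(0.5, 0.5))
        pg = param_gradient(harmonic_snaps(0.5, seed=11, n_steps=120000),
                            space, BETA1)
        exact_k1 = harmonic_dudl_dk1_exact(K0, K1, 0.5, 1.0)
        assert exact_k1 == pytest.approx(0.08)
        i = pg.names.index("k1")
        assert abs(pg.grad[i] - exact_k1) < 3 * pg.se[i]
        # d/dk0: differentiate the closed form, d k_a/d k0 = 1 - a
        ka = 2.5
        exact_k0 = -1.0 / (2 * ka) - (1 - 0.5) * (K1 - K0) / (2 * ka * ka)
        j = pg.names.index("k0")
        assert abs(pg.grad[j] - exact_k0) < 3 * pg.se[j]

    def test_uncoupled_parameter_has_zero_gradient(self, tiny_lj_box, state,
                                                   fast_sampler):
        """A parameter bound to a species absent from the system cannot
        move any energy: its gradient is identically zero."""
        space = ParameterSpace.create(
            ("solute.epsilon", "ghost.epsilon"), ("epsilon", "epsilon"),
            (2.0, 1.0))
        cp = CoupledPotential(mode="linear", stage="vdw")
        snaps = metropolis_sample(tiny_lj_box, cp, 0.8, state, fast_sampler,
                                  space, space.K0)
        pg = param_gradient(snaps, space, state, space.K0)
        i = pg.names.index("ghost.epsilon")
        assert pg.grad[i] == 0.0

    def test_lj_energy_linear_in_epsilon(self, tiny_lj_box):
        """Per-snapshot finite difference reproduces dU/de = U/e exactly
        for a single-epsilon pair interaction (LJ is linear in epsilon)."""
        space = ParameterSpace.create(("solute.epsilon",), ("epsilon",),
                                      (2.0,))
        cp = CoupledPotential(mode="linear", stage="vdw")
        from fegrad.toysim import ToyEngine
        eng = ToyEngine(tiny_lj_box, cp, space)
        pos = tiny_lj_box.positions[None]
        du = eng.delta_u_batch(pos, np.array([2.0]))[0]
        h = 1e-4 * 2.0
        fd = (eng.delta_u_batch(pos, np.array([2.0 + h]))[0]
              - eng.delta_u_batch(pos, np.array([2.0 - h]))[0]) / (2 * h)
        # d sqrt(e_u e_s)/d e_u = sqrt(e_s/e_u)/2  =>  dU/de_u = U/(2 e_u)
        assert fd == pytest.approx(du / (2 * 2.0), rel=1e-6)

    def test_engine_without_bound_space_rejected(self, tiny_lj_box, state,
                                                 fast_sampler):
        cp = CoupledPotential(mode="linear", stage="vdw")
        snaps = metropolis_sample(tiny_lj_box, cp, 0.8, state, fast_sampler)
        space = ParameterSpace.create(("solute.epsilon",), ("epsilon",), (2.0,))
        with pytest.raises(ValueError, match="bound ParameterSpace"):
            param_gradient(snaps, space, state)


class TestSchedulesAndIO:
    def test_vdw_grid_clusters_towards_full_coupling(self):
        g = vdw_alpha_grid(11)
        assert g[0] == 0.0 and g[-1] == 1.0
        spacings = np.diff(g)
        assert np.all(np.diff(spacings) < 0)

    def test_stage_grid_must_span_unit_interval(self, fast_sampler):
        with pytest.raises(ValueError, match="span"):
            Stage(CoupledPotential(), np.array([0.0, 0.5]), fast_sampler)

    def test_schedule_rejects_double_scaled_interactions(self, fast_sampler):
        vdw = Stage(CoupledPotential(mode="linear", stage="vdw"),
                    np.linspace(0, 1, 3), fast_sampler)
        both = Stage(CoupledPotential(mode="linear", stage="combined"),
                     np.linspace(0, 1, 3), fast_sampler)
        with pytest.raises(ValueError, match="two stages"):
            AlphaSchedule((vdw, both))

    def test_fit_grid_need_not_span(self, fast_sampler):
        g = FitGrid(CoupledPotential(), np.array([0.4, 0.7, 1.0]),
                    fast_sampler)
        assert g.alphas[0] == 0.4

    def test_gradient_table_round_trip(self, tmp_path):
        ests = [GradientEstimate(a, -2.0 * a, 0.1, 10) for a in (0.2, 0.6, 1.0)]
        path = tmp_path / "grads.csv"
        write_gradient_table(path, "mol", "vdw", ests)
        df = read_gradient_table(path)
        assert list(df["alpha"]) == [0.2, 0.6, 1.0]
        assert df["dudl_mean"].iloc[2] == -2.0

    def test_gradient_table_schema_enforced(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("alpha,mean\n0.1,2\n")
        with pytest.raises(ValueError, match="schema"):
            read_gradient_table(path)
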