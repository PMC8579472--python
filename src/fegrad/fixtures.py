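"""Synthetic reference targets and end-to-end parameter-recovery runs.

The desk-scale verification surface of the whole method: a "reference"
model (the toy engine run at known ground-truth parameters K*) plays the
role of the higher-resolution simulations that supply free-energy-gradient
targets; the fit phase perturbs the parameters, re-simulates, and must
recover the truth.  Because truth is known by construction, recovery
quality is measurable in absolute terms.

The reference and fit phases draw from disjoint seed streams, so the fit
can never "remember" the reference noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alchemy, objective as obj_mod, optimizer as opt_mod
from .alchemy import (AlphaSchedule, FDConfig, FitGrid, SamplerConfig,
                      Stage, derive_seed, estimate_dudl,
                      hydration_free_energy, param_gradient, run_stage,
                      vdw_alpha_grid)
from .forcefield import ParameterSpace
from .objective import TargetSpec, evaluate_objective, objective_derivatives
from .optimizer import ObjectiveEval, OptimizationTrace, TrustConfig, optimize
from .toysim import (CoupledPotential, Species, ThermoState, ToySystem,
                     build_solvation_box, metropolis_sample)


@dataclass(frozen=True)
class RecoveryScenario:
    """A self-consistent parameter-recovery experiment definition.

    ``perturbation`` maps parameter names to offsets in units of their
    prior widths; the fit starts (and centres its prior) at
    K* + offset * t.  ``seed_ref`` and ``seed_fit`` are independent
    streams for the two phases.
    """

    name: str
    space: ParameterSpace            # ground-truth values in K0
    system: ToySystem
    state: ThermoState
    fit_grids: tuple[FitGrid, ...]   # where <dU>_a is matched (linear path)
    schedule: AlphaSchedule          # TI schedule for hydration free energies
    perturbation: dict[str, float]
    seed_ref: int = 2024
    seed_fit: int = 4048
    n_repeat: int = 3
    w_reg: float = obj_mod.DEFAULT_W_REG

    def __post_init__(self):
        if self.seed_ref == self.seed_fit:
            raise ValueError("reference and fit phases need distinct seeds")
        if not self.perturbation:
            raise ValueError("scenario must name at least one parameter to "
                             "perturb (zero magnitude = start at truth)")

    @property
    def truth_K(self) -> np.ndarray:
        return self.space.K0.copy()

    def initial_space(self) -> ParameterSpace:
        """Parameter space recentred at the perturbed starting values."""
        K = self.space.K0.copy()
        for name, mult in self.perturbation.items():
            i = self.space.index(name)
            K[i] = K[i] + mult * self.space.t[i]
        return self.space.with_K0(K)


def canonical_scenario(n_solvent: int = 100, seed_ref: int = 2024,
                       seed_fit: int = 4048,
                       sampler: SamplerConfig | None = None
                       ) -> RecoveryScenario:
    """The packaged regression scenario: a 1-bead apolar solute
    (sigma 0.47 nm, epsilon 2.0 kJ/mol, q 0) in a 100-particle LJ solvent
    at 298.15 K, epsilon perturbed by +20% (0.8 prior widths at t = 0.5).

    Fitting matches <dU>_a on the linear path: a 5-point uniform
    electrostatic grid (retained although the solute is neutral, so the
    staged machinery is exercised end to end) and an 11-point vdW grid on
    [0.4, 1.0] clustered towards full coupling.  The linear path's
    insertion-energy mean diverges at the decoupled end and its variance
    explodes at low alpha, so fitting grids stay in the informative upper
    window (mirroring the alpha window used for correction gradients).
    Hydration free energies integrate the soft-core vdW path over the full
    [0, 1] range.

    The epsilon prior width is 2.0 kJ/mol (the parameter's own magnitude):
    the method's premise is that the starting parameters may be badly
    wrong, so the prior is an intentionally weak guard against runaway
    rather than an informative constraint — a tighter prior would bias the
    recovered value towards the (deliberately wrong) starting point.
    """
    solute = Species("solute", sigma=0.47, epsilon=2.0, charge=0.0,
                     role="solute")
    solvent = Species("solvent", sigma=0.42, epsilon=0.8, charge=0.0)
    system = build_solvation_box(solute, {solvent: n_solvent}, L=2.5,
                                 r_c=0.9, seed=7, tether_k=10.0)
    space = ParameterSpace.create(
        names=("solute.sigma", "solute.epsilon", "solute.charge"),
        kinds=("sigma", "epsilon", "charge"),
        K0=(0.47, 2.0, 0.0),
        t=(0.05, 2.0, 0.1),
        frozen=(True, False, True))
    sampler = sampler or SamplerConfig(seed=0, n_equil=12000,
                                       n_steps=480000, save_every=1600)
    fit_grids = (
        FitGrid(CoupledPotential(mode="linear", stage="electrostatic"),
                np.linspace(0, 1, 5), sampler),
        FitGrid(CoupledPotential(mode="linear", stage="vdw"),
                vdw_alpha_grid(11, lo=0.4), sampler),
    )
    schedule = AlphaSchedule.default(sampler, n_elec=5, n_vdw=11)
    return RecoveryScenario(
        name="canonical-1bead", space=space, system=system,
        state=ThermoState(T=298.15), fit_grids=fit_grids, schedule=schedule,
        perturbation={"solute.epsilon": 0.2},   # +20% of epsilon = 0.4 kJ/mol
        seed_ref=seed_ref, seed_fit=seed_fit, n_repeat=3)


def charged_toy_system(n_plus: int = 48, n_minus: int = 53,
                       ) -> tuple[ToySystem, ParameterSpace, ThermoState]:
    """A charged variant of the toy box for exercising electrostatics.

    One +1e solute bead in a mixed +-0.2e single-site solvent (an
    overall-neutral molten-salt-like bath) so that sigma, epsilon *and*
    charge parameters all carry signal in the coupled stages.
    """
    solute = Species("solute", sigma=0.47, epsilon=2.0, charge=1.0,
                     role="solute")
    solv_p = Species("solv_p", sigma=0.42, epsilon=0.8, charge=0.2)
    solv_m = Species("solv_m", sigma=0.42, epsilon=0.8, charge=-0.2)
    system = build_solvation_box(solute, {solv_p: n_plus, solv_m: n_minus},
                                 L=2.5, r_c=0.9, seed=11, tether_k=10.0)
    space = ParameterSpace.create(
        names=("solute.sigma", "solute.epsilon", "solute.charge"),
        kinds=("sigma", "epsilon", "charge"),
        K0=(0.47, 2.0, 1.0))
    return system, space, ThermoState(T=298.15)


def bruteforce_param_gradient(system: ToySystem, coupled: CoupledPotential,
                              alpha: float, state: ThermoState,
                              space: ParameterSpace, K: np.ndarray,
                              index: int, step: float,
                              sampler: SamplerConfig, n_blocks: int = 10
                              ) -> tuple[float, float]:
    """Independent oracle for d<dU>_a/dK_i: re-simulate at K_i +/- step and
    central-difference the two <dU>_a means.

    The two runs share the random move sequence (common random numbers),
    so much of the sampling noise cancels in the difference; the SE is the
    block standard error of the paired per-block differences.  Returns
    ``(gradient, se)``.
    """
    from .alchemy import block_average

    Kp, Km = np.asarray(K, float).copy(), np.asarray(K, float).copy()
    Kp[index] += step
    Km[index] -= step
    sp = metropolis_sample(system, coupled, alpha, state, sampler, space, Kp)
    sm = metropolis_sample(system, coupled, alpha, state, sampler, space, Km)
    diff = (sp.delta_u - sm.delta_u) / (2.0 * step)
    mean, se, _ = block_average(diff, n_blocks)
    return mean, se


# -- reference-phase targets ----------------------------------------------


def generate_reference_targets(scenario: RecoveryScenario,
                               outdir: str | Path | None = None
                               ) -> list[TargetSpec]:
    """Run the engine at the ground-truth parameters over the fitting
    grids and package the <dU>_a estimates as targets (one per grid).

    Fully reproducible from the scenario seeds; with ``outdir`` the tables
    are also written as CSV.
    """
    targets = []
    for s_idx, grid in enumerate(scenario.fit_grids):
        est = run_stage(scenario.system, grid, scenario.state,
                        derive_seed(scenario.seed_ref, s_idx),
                        scenario.space, scenario.truth_K)
        target = TargetSpec(
            molecule=scenario.name, stage=grid.coupled.stage,
            alphas=np.array([e.alpha for e in est]),
            ref_mean=np.array([e.mean for e in est]),
            ref_se=np.array([e.se for e in est]))
        targets.append(target)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            target.to_csv(outdir / f"target_{scenario.name}_{target.stage}.csv")
    return targets


def reference_hfe(scenario: RecoveryScenario):
    """Hydration free energy at the ground truth (reference phase seeds)."""
    return hydration_free_energy(
        scenario.system, scenario.schedule, scenario.state,
        scenario.space, scenario.truth_K, n_repeat=scenario.n_repeat,
        seed=derive_seed(scenario.seed_ref, 999))


# -- the fit-phase objective callback --------------------------------------


class FitProblem:
    """Simulation-backed objective over mathematical coordinates.

    Every evaluation re-simulates each target stage at the current
    physical parameters (fresh seeds per evaluation, as a real fit would),
    estimates <dU>_a and its parameter gradients from the same snapshots,
    and assembles the regularised objective with derivatives.
    """

    def __init__(self, scenario: RecoveryScenario, targets: list[TargetSpec],
                 fit_space: ParameterSpace):
        self.scenario = scenario
        self.targets = targets
        self.space = fit_space
        self.n_evaluations = 0
        self.sensitivity_log: list[dict] = []

    def __call__(self, k: np.ndarray) -> ObjectiveEval:
        sc = self.scenario
        K = self.space.map_to_physical(k)
        eval_idx = self.n_evaluations
        self.n_evaluations += 1
        estimates, grads = [], []
        for s_idx, grid in enumerate(sc.fit_grids):
            stage_est, stage_grads = [], []
            for j, alpha in enumerate(grid.alphas):
                cfg = SamplerConfig(
                    seed=derive_seed(sc.seed_fit, eval_idx, s_idx, j),
                    n_equil=grid.sampler.n_equil,
                    n_steps=grid.sampler.n_steps,
                    save_every=grid.sampler.save_every,
                    max_displacement=grid.sampler.max_displacement)
                snaps = metropolis_sample(sc.system, grid.coupled,
                                          float(alpha), sc.state, cfg,
                                          self.space, K)
                stage_est.append(estimate_dudl(snaps))
                stage_grads.append(param_gradient(snaps, self.space,
                                                  sc.state, K))
            estimates.append(stage_est)
            grads.append(stage_grads)
        report = objective_derivatives(k, self.targets, self.space,
                                       estimates, grads, sc.w_reg)
        self._log_sensitivity(grads)
        # CG-side sampling noise contributes alongside the reference SEs
        cg_noise = sum(
            float(np.sum(t.weights * (np.array([e.se for e in est]) / t.d) ** 2))
            for t, est in zip(self.targets, estimates))
        return ObjectiveEval(value=report.total, gradient=report.gradient,
                             hessian=report.hessian,
                             noise_floor=report.noise_floor + cg_noise)

    def _log_sensitivity(self, grads) -> None:
        """Track the best per-point |gradient|/SE per parameter: the
        identifiability signal (a parameter is informative if its gradient
        rises clearly above its own statistical error somewhere)."""
        entry = {}
        for name_idx, name in enumerate(
                self.space.names[i] for i in self.space.free_indices):
            z_best = 0.0
            for stage_grads in grads:
                for pg in stage_grads:
                    se = pg.se[name_idx]
                    z = abs(pg.grad[name_idx]) / se if se > 0 else \
                        (np.inf if pg.grad[name_idx] != 0 else 0.0)
                    z_best = max(z_best, z)
            entry[name] = z_best
        self.sensitivity_log.append(entry)

    def parameter_uncertainty(self, k: np.ndarray) -> np.ndarray:
        """Propagated statistical uncertainty of the solution, in k units.

        Linearises the stationarity condition: cov(k) =
        H^-1 (4 J^T W S W J) H^-1 with S the per-point variance of the
        residuals (reference SE^2 + current-model SE^2)/d^2.  Returns the
        square-root diagonal.  Evaluated with fresh simulations at ``k``.
        """
        sc = self.scenario
        K = self.space.map_to_physical(k)
        eval_idx = self.n_evaluations
        self.n_evaluations += 1
        rows, svar, wvec = [], [], []
        for s_idx, grid in enumerate(sc.fit_grids):
            target = self.targets[s_idx]
            for j, alpha in enumerate(grid.alphas):
                cfg = SamplerConfig(
                    seed=derive_seed(sc.seed_fit, eval_idx, s_idx, j),
                    n_equil=grid.sampler.n_equil,
                    n_steps=grid.sampler.n_steps,
                    save_every=grid.sampler.save_every,
                    max_displacement=grid.sampler.max_displacement)
                snaps = metropolis_sample(sc.system, grid.coupled,
                                          float(alpha), sc.state, cfg,
                                          self.space, K)
                est = estimate_dudl(snaps)
                pg = param_gradient(snaps, self.space, sc.state, K)
                t_free = self.space.t[self.space.free_indices]
                rows.append(t_free * pg.grad / target.d)
                svar.append((target.ref_se[j] ** 2 + est.se ** 2) / target.d ** 2)
                wvec.append(target.weights[j])
        J = np.array(rows)
        w = np.array(wvec)
        S = np.array(svar)
        H = 2.0 * (J.T * w) @ J + 2.0 * sc.w_reg * np.eye(J.shape[1])
        M = 4.0 * (J.T * (w * S * w)) @ J
        Hinv = np.linalg.inv(H)
        cov = Hinv @ M @ Hinv
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# -- recovery experiment ---------------------------------------------------


@dataclass
class RecoveryReport:
    """Outcome of a parameter-recovery experiment."""

    scenario: str
    param_names: list[str]
    truth_K: list[float]
    initial_K: list[float]
    recovered_K: list[float]
    uncertainty_K: list[float]
    param_ok: list[bool]
    objective_initial: float
    objective_best: float
    reduction_factor: float
    noise_floor: float
    n_accepted_iterations: int
    termination_reason: str
    dg_reference: float
    dg_reference_se: float
    dg_refit: float
    dg_refit_se: float
    dg_zscore: float
    hfe_ok: bool
    non_identifiable: list[str]
    warnings: list[str]
    success: bool
    diverged: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    def summary(self) -> str:
        lines = [f"Recovery experiment: {self.scenario}",
                 f"  termination: {self.termination_reason} "
                 f"({self.n_accepted_iterations} accepted iterations)"]
        for n, kt, ki, kr, u, ok in zip(self.param_names, self.truth_K,
                                        self.initial_K, self.recovered_K,
                                        self.uncertainty_K, self.param_ok):
            lines.append(f"  {n}: truth {kt:.4f}  start {ki:.4f}  "
                         f"recovered {kr:.4f} +/- {u:.4f}  "
                         f"[{'ok' if ok else 'MISS'}]")
        lines.append(f"  objective: {self.objective_initial:.4g} -> "
                     f"{self.objective_best:.4g} "
                     f"({self.reduction_factor:.1f}x reduction, "
                     f"noise floor {self.noise_floor:.2g})")
        lines.append(f"  dG_hyd: reference {self.dg_reference:.3f} +/- "
                     f"{self.dg_reference_se:.3f}, refit {self.dg_refit:.3f} "
                     f"+/- {self.dg_refit_se:.3f} (z = {self.dg_zscore:.2f}) "
                     f"[{'ok' if self.hfe_ok else 'MISS'}]")
        if self.non_identifiable:
            lines.append(f"  non-identifiable: {self.non_identifiable}")
        lines.append(f"  success: {self.success}")
        return "\n".join(lines)


def recovery_experiment(scenario: RecoveryScenario,
                        trust: TrustConfig | None = None,
                        targets: list[TargetSpec] | None = None
                        ) -> RecoveryReport:
    """Generate reference targets, perturb, optimise, and audit recovery.

    Success requires every unfrozen parameter within
    max(5%, 2 x propagated uncertainty) of truth and the refit hydration
    free energy within 3 combined SE of the reference-phase value.
    Optimisation divergence is reported, not raised.
    """
    trust = trust or TrustConfig()
    if targets is None:
        targets = generate_reference_targets(scenario)
    fit_space = scenario.initial_space()
    problem = FitProblem(scenario, targets, fit_space)

    diverged = False
    try:
        trace = optimize(problem, np.zeros(fit_space.n_free), trust)
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        return _divergence_report(scenario, fit_space, str(exc))

    best_k = trace.best_k
    K_rec = fit_space.map_to_physical(best_k)
    sigma_k = problem.parameter_uncertainty(best_k)
    free = fit_space.free_indices
    t_free = fit_space.t[free]
    sigma_K = sigma_k * t_free

    # identifiability: a parameter whose gradient never rose above twice its
    # own statistical error at any alpha point carries no usable signal
    non_ident = []
    for name in (fit_space.names[i] for i in free):
        z_best = max(e[name] for e in problem.sensitivity_log)
        if z_best < 2.0:
            non_ident.append(name)

    truth_K = scenario.truth_K
    names, ok_flags, rec_list, unc_list, truth_list, init_list = \
        [], [], [], [], [], []
    for out_i, i in enumerate(free):
        names.append(fit_space.names[i])
        truth, rec = truth_K[i], K_rec[i]
        tol = max(0.05 * abs(truth), 2.0 * sigma_K[out_i])
        ok_flags.append(bool(abs(rec - truth) <= tol))
        rec_list.append(float(rec))
        unc_list.append(float(sigma_K[out_i]))
        truth_list.append(float(truth))
        init_list.append(float(fit_space.K0[i]))

    L0 = trace.records[0].value
    Lb = trace.best_value
    reduction = L0 / Lb if Lb > 0 else np.inf
    ref_noise_floor = sum(
        float(np.sum(t.weights * (t.ref_se / t.d) ** 2)) for t in targets)

    dg_ref = reference_hfe(scenario)
    dg_fit = hydration_free_energy(
        scenario.system, scenario.schedule, scenario.state, fit_space, K_rec,
        n_repeat=scenario.n_repeat, seed=derive_seed(scenario.seed_fit, 999))
    combined_se = float(np.hypot(dg_ref.se, dg_fit.se))
    z = (dg_fit.total - dg_ref.total) / combined_se if combined_se > 0 else 0.0
    hfe_ok = bool(abs(z) < 3.0)

    success = bool(all(ok_flags) and hfe_ok and not non_ident and not diverged)
    return RecoveryReport(
        scenario=scenario.name, param_names=names, truth_K=truth_list,
        initial_K=init_list, recovered_K=rec_list, uncertainty_K=unc_list,
        param_ok=ok_flags, objective_initial=float(L0),
        objective_best=float(Lb), reduction_factor=float(reduction),
        noise_floor=float(ref_noise_floor),
        n_accepted_iterations=trace.n_accepted,
        termination_reason=trace.reason, dg_reference=float(dg_ref.total),
        dg_reference_se=float(dg_ref.se), dg_refit=float(dg_fit.total),
        dg_refit_se=float(dg_fit.se), dg_zscore=float(z), hfe_ok=hfe_ok,
        non_identifiable=non_ident, warnings=list(trace.warnings),
        success=success, diverged=diverged)


def _divergence_report(scenario, fit_space, message: str) -> RecoveryReport:
    free = fit_space.free_indices
    names = [fit_space.names[i] for i in free]
    nan = float("nan")
    return RecoveryReport(
        scenario=scenario.name, param_names=names,
        truth_K=[float(scenario.truth_K[i]) for i in free],
        initial_K=[float(fit_space.K0[i]) for i in free],
        recovered_K=[nan] * len(names), uncertainty_K=[nan] * len(names),
        param_ok=[False] * len(names), objective_initial=nan,
        objective_best=nan, reduction_factor=nan, noise_floor=nan,
        n_accepted_iterations=0,
        termination_reason=f"diverged: {message}", dg_reference=nan,
        dg_reference_se=nan, dg_refit=nan, dg_refit_se=nan, dg_zscore=nan,
        hfe_ok=False, non_identifiable=[], warnings=[], success=False,
        diverged=True)
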