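"""Free-energy gradients, thermodynamic integration and parameter derivatives.

The fitting datum of the whole package is the *free-energy gradient*
``<dU>_a``: the ensemble average, in the alpha-coupled ensemble, of the
instantaneous energy gap ``dU = U_1 - U_0``.  For the linear coupling path
this equals the TI integrand ``<dU/da>_a``, so the free-energy difference
between the end states is

    dF = integral_0^1 <dU>_a da.

The derivative of ``<dU>_a`` with respect to a force-field parameter
``lambda`` follows from differentiating the ensemble average and is the
fluctuation identity

    d<dU>_a/dl = <d(dU)/dl>_a
                 - beta * ( <dU * dE_a/dl>_a - <dU>_a <dE_a/dl>_a ),

where ``E_a`` is the sampled potential at coupling ``a``.  Both
per-snapshot derivatives are obtained by central finite differences over
parameter perturbations; uncertainties come from block averaging of the
full combined estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from .forcefield import ParameterSpace
from .toysim import (CoupledPotential, SamplerConfig, SnapshotSet, ThermoState,
                     ToySystem, metropolis_sample)

GRADIENT_SCHEMA = "# fegrad-gradients v1"


# -- block averaging -------------------------------------------------------


def block_average(x: np.ndarray, n_blocks: int = 10) -> tuple[float, float, int]:
    """Mean and standard error of a correlated series by block averaging.

    The series is split into ``n_blocks`` contiguous blocks (reduced so that
    each block holds at least two samples, floor of 5 blocks); the SE is the
    standard deviation of block means over sqrt(n_blocks).  Returns
    ``(mean, se, n_blocks_used)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for block averaging")
    b = int(min(n_blocks, n // 2))
    b = max(b, 5)
    usable = (n // b) * b
    blocks = x[:usable].reshape(b, -1).mean(axis=1)
    se = float(np.std(blocks, ddof=1) / np.sqrt(b))
    return float(np.mean(x)), se, b


# -- gradient estimates ----------------------------------------------------


@dataclass(frozen=True)
class GradientEstimate:
    """<dU>_a at one alpha: mean, block-averaged SE, effective samples."""

    alpha: float
    mean: float
    se: float
    n_eff: int


def estimate_dudl(snapshots: SnapshotSet, n_blocks: int = 10
                  ) -> GradientEstimate:
    """Estimate the free-energy gradient at the snapshot set's alpha.

    Uses the cached TI integrand, which for linear coupling is exactly the
    instantaneous gap dU (the fitting datum <dU>_a).
    """
    if snapshots.n_snapshots < 10:
        raise ValueError("need at least 10 snapshots")
    mean, se, b = block_average(snapshots.dudalpha, n_blocks)
    return GradientEstimate(alpha=snapshots.alpha, mean=mean, se=se, n_eff=b)


# -- thermodynamic integration ---------------------------------------------


@dataclass(frozen=True)
class StageResult:
    """Integrated dF over one stage with SE propagated through quadrature."""

    name: str
    delta_f: float
    se: float
    rule: str
    alphas: np.ndarray
    weights: np.ndarray


def trapezoid_weights(alphas: np.ndarray) -> np.ndarray:
    w = np.zeros_like(alphas)
    d = np.diff(alphas)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def gauss_legendre_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights mapped from [-1, 1] to [0, 1]."""
    x, w = legendre.leggauss(n)
    return (x + 1) / 2, w / 2


def ti_integrate(estimates: list[GradientEstimate], rule: str = "trapezoid",
                 name: str = "stage") -> StageResult:
    """Integrate <dU>_a over alpha for one stage.

    ``rule`` is ``"trapezoid"`` (any sorted grid) or ``"gauss-legendre"``
    (the grid must be the Gauss-Legendre nodes for its size).  The SE is
    the quadrature-weighted root-sum-square of the per-point SEs.
    """
    alphas = np.array([e.alpha for e in estimates], dtype=float)
    if np.any(np.diff(alphas) <= 0):
        raise ValueError("alpha values must be strictly increasing")
    if np.any((alphas < 0) | (alphas > 1)):
        raise ValueError("alpha values must lie in [0, 1]")
    means = np.array([e.mean for e in estimates])
    ses = np.array([e.se for e in estimates])
    if rule == "trapezoid":
        w = trapezoid_weights(alphas)
    elif rule == "gauss-legendre":
        nodes, w = gauss_legendre_grid(len(alphas))
        if not np.allclose(alphas, nodes, atol=1e-9):
            raise ValueError("grid does not match Gauss-Legendre nodes")
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    delta_f = float(w @ means)
    se = float(np.sqrt(np.sum((w * ses) ** 2)))
    return StageResult(name=name, delta_f=delta_f, se=se, rule=rule,
                       alphas=alphas, weights=w)


# -- alpha schedules -------------------------------------------------------


def vdw_alpha_grid(n: int = 11, ratio: float = 0.75, lo: float = 0.0
                   ) -> np.ndarray:
    """A [lo, 1] grid whose spacings shrink geometrically towards alpha = 1.

    The fully coupled end dominates the integrand for cavity growth, so
    points cluster there.  A non-zero ``lo`` is used for *fitting* grids on
    the linear path, which is singular at the decoupled end (the mean of
    the unweighted insertion energy diverges); TI quadrature grids keep
    lo = 0 and pair with the soft-core path.
    """
    steps = ratio ** np.arange(n - 1)
    alphas = np.concatenate([[0.0], np.cumsum(steps)])
    return lo + (1.0 - lo) * alphas / alphas[-1]


@dataclass(frozen=True)
class FitGrid:
    """Alpha points at which <dU>_a is matched between models.

    Unlike a TI :class:`Stage`, a fitting grid need not span [0, 1]: the
    fitting data are individual ensemble averages, not a quadrature.
    """

    coupled: CoupledPotential
    alphas: np.ndarray
    sampler: SamplerConfig

    def __post_init__(self):
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if a.size < 1 or np.any((a < 0) | (a > 1)):
            raise ValueError("fit grid must contain points within [0, 1]")
        if np.any(np.diff(a) <= 0):
            raise ValueError("fit grid must be strictly increasing")


@dataclass(frozen=True)
class Stage:
    """One decoupling stage: a coupled-potential definition and its grid."""

    coupled: CoupledPotential
    alphas: np.ndarray
    sampler: SamplerConfig

    def __post_init__(self):
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if a.size < 2 or a[0] != 0.0 or a[-1] != 1.0:
            raise ValueError("stage grid must contain >= 2 points spanning [0, 1]")
        if np.any(np.diff(a) <= 0):
            raise ValueError("stage grid must be strictly increasing")


@dataclass(frozen=True)
class AlphaSchedule:
    """Ordered stages covering all solute-solvent interactions exactly once."""

    stages: tuple[Stage, ...]

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        seen: set[str] = set()
        for st in self.stages:
            comps = {"vdw": {"vdw"}, "electrostatic": {"coulomb"},
                     "combined": {"vdw", "coulomb"}}[st.coupled.stage]
            if comps & seen:
                raise ValueError("an interaction is scaled in two stages")
            seen |= comps

    @classmethod
    def default(cls, sampler: SamplerConfig, n_elec: int = 5, n_vdw: int = 11,
                mode: str = "softcore") -> "AlphaSchedule":
        """Electrostatic stage (uniform grid, linear) then vdW stage
        (end-clustered grid, soft-core by default: the linear vdW path has
        a divergent integrand at the decoupled end)."""
        elec = Stage(CoupledPotential(mode="linear", stage="electrostatic"),
                     np.linspace(0, 1, n_elec), sampler)
        vdw = Stage(CoupledPotential(mode=mode, stage="vdw"),
                    vdw_alpha_grid(n_vdw), sampler)
        return cls((elec, vdw))


@dataclass(frozen=True)
class TIResult:
    """Hydration free energy from staged decoupling.

    Sign convention (recorded): stages integrate from the decoupled
    reference (alpha = 0) to the fully interacting state (alpha = 1), so
    the total dF *is* dG_hyd = -dF(decoupling).
    """

    stages: tuple[StageResult, ...]
    total: float
    se: float
    convention: str = "dG_hyd = dF(coupling 0->1) = -dF(decoupling)"
    replicates: tuple[float, ...] = ()
    se_repeats: float = 0.0     # standard error across repeat simulations
    se_propagated: float = 0.0  # quadrature-propagated, per mean of repeats

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "replicates", tuple(self.replicates))


def derive_seed(*entropy: int) -> int:
    """Collision-free child seed from an entropy tuple (SeedSequence)."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0])


def run_stage(system: ToySystem, stage: Stage, state: ThermoState,
              seed: int, space=None, K=None) -> list[GradientEstimate]:
    """Sample every alpha point of a stage and estimate <dU>_a at each."""
    estimates = []
    for j, alpha in enumerate(stage.alphas):
        cfg = SamplerConfig(seed=derive_seed(seed, j),
                            n_equil=stage.sampler.n_equil,
                            n_steps=stage.sampler.n_steps,
                            save_every=stage.sampler.save_every,
                            max_displacement=stage.sampler.max_displacement)
        try:
            snaps = metropolis_sample(system, stage.coupled, float(alpha),
                                      state, cfg, space, K)
            estimates.append(estimate_dudl(snaps))
        except Exception as exc:
            raise RuntimeError(
                f"sampling failed at alpha={alpha:g}: {exc}") from exc
    return estimates


def hydration_free_energy(system: ToySystem, schedule: AlphaSchedule,
                          state: ThermoState, space=None, K=None,
                          n_repeat: int = 3, seed: int = 0,
                          rule: str = "trapezoid") -> TIResult:
    """Hydration free energy by staged alchemical coupling.

    The whole calculation is repeated ``n_repeat`` times with distinct
    seeds.  The reported SE is the more conservative of the across-repeat
    standard error and the quadrature-propagated SE scaled to the repeat
    mean: with few repeats the empirical SE is itself highly uncertain
    (chi-distributed with n-1 degrees of freedom), so taking the maximum
    guards against fluky tight triplets.
    """
    totals, prop_vars = [], []
    stage_results_last = None
    for rep in range(n_repeat):
        stage_results = []
        for s_idx, stage in enumerate(schedule.stages):
            est = run_stage(system, stage, state,
                            derive_seed(seed, rep, s_idx), space, K)
            stage_results.append(
                ti_integrate(est, rule=rule, name=stage.coupled.stage))
        totals.append(sum(sr.delta_f for sr in stage_results))
        prop_vars.append(sum(sr.se ** 2 for sr in stage_results))
        stage_results_last = stage_results
    totals = np.array(totals)
    se_prop = float(np.sqrt(np.mean(prop_vars) / n_repeat))
    if n_repeat > 1:
        se_rep = float(np.std(totals, ddof=1) / np.sqrt(n_repeat))
    else:
        se_rep = 0.0
    return TIResult(stages=tuple(stage_results_last),
                    total=float(np.mean(totals)),
                    se=max(se_rep, se_prop),
                    replicates=tuple(totals),
                    se_repeats=se_rep, se_propagated=se_prop)


# -- parameter derivatives of <dU>_a ---------------------------------------


@dataclass(frozen=True)
class FDConfig:
    """Central finite-difference step control: h = max(abs_floor, rel*|K|)."""

    rel_step: float = 1e-4
    abs_floor: float = 1e-6


@dataclass(frozen=True)
class ParamGradientEstimate:
    """d<dU>_a/dl per unfrozen parameter with block-averaged SEs."""

    alpha: float
    grad: np.ndarray      # (n_free,)
    se: np.ndarray        # (n_free,)
    steps: np.ndarray     # (n_free,) finite-difference steps used
    names: tuple[str, ...]


def param_gradient(snapshots: SnapshotSet, space: ParameterSpace,
                   state: ThermoState, K: np.ndarray | None = None,
                   fd: FDConfig = FDConfig(), n_blocks: int = 10
                   ) -> ParamGradientEstimate:
    """Analytic derivative of <dU>_a w.r.t. each unfrozen parameter.

    Implements the fluctuation identity (module docstring) with the
    per-snapshot derivatives of ``dU`` and ``E_a`` obtained by central
    finite differences through the snapshot set's engine.  The SE of each
    component is the block standard error of the combined estimator.
    """
    engine = snapshots.engine
    if getattr(engine, "space", "absent") is None:
        raise ValueError(
            "snapshot engine has no bound ParameterSpace; sample with "
            "space= to enable parameter derivatives")
    beta = state.beta
    alpha = snapshots.alpha
    pos = snapshots.positions
    K = space.K0.copy() if K is None else np.asarray(K, float).copy()
    du = snapshots.delta_u
    free = space.free_indices
    n_free = free.size
    grads = np.zeros(n_free)
    ses = np.zeros(n_free)
    steps = np.zeros(n_free)

    _, _, b = block_average(du, n_blocks)
    usable = (du.size // b) * b

    for out_i, i in enumerate(free):
        h = max(fd.abs_floor, fd.rel_step * abs(K[i]))
        space.perturb(i, h)  # validates the step against parameter bounds
        Kp, Km = K.copy(), K.copy()
        Kp[i] += h
        Km[i] -= h
        ddu = (engine.delta_u_batch(pos, Kp) - engine.delta_u_batch(pos, Km)) / (2 * h)
        if hasattr(engine, "e_alpha_fd_diff"):
            dea = engine.e_alpha_fd_diff(pos, alpha, Kp, Km) / (2 * h)
        else:
            dea = (engine.e_alpha_batch(pos, alpha, Kp)
                   - engine.e_alpha_batch(pos, alpha, Km)) / (2 * h)
        grads[out_i] = _fluctuation_estimator(du, ddu, dea, beta)
        # block SE of the combined (non-linear) estimator
        du_b = du[:usable].reshape(b, -1)
        ddu_b = ddu[:usable].reshape(b, -1)
        dea_b = dea[:usable].reshape(b, -1)
        per_block = np.array([
            _fluctuation_estimator(du_b[j], ddu_b[j], dea_b[j], beta)
            for j in range(b)])
        ses[out_i] = float(np.std(per_block, ddof=1) / np.sqrt(b))
        steps[out_i] = h
    return ParamGradientEstimate(alpha=alpha, grad=grads, se=ses, steps=steps,
                                 names=tuple(space.names[i] for i in free))


def _fluctuation_estimator(du, ddu, dea, beta) -> float:
    cov = np.mean(du * dea) - np.mean(du) * np.mean(dea)
    return float(np.mean(ddu) - beta * cov)


# -- CSV interchange -------------------------------------------------------


def write_gradient_table(path: str | Path, molecule: str, stage: str,
                         estimates: list[GradientEstimate],
                         param_grads: list[ParamGradientEstimate] | None = None
                         ) -> None:
    """Write a <dU>_a table (optionally with parameter-gradient columns)."""
    rows = []
    for j, e in enumerate(estimates):
        row = {"molecule": molecule, "stage": stage, "alpha": e.alpha,
               "dudl_mean": e.mean, "dudl_se": e.se, "n_eff": e.n_eff}
        if param_grads is not None:
            pg = param_grads[j]
            for name, g, s in zip(pg.names, pg.grad, pg.se):
                row[f"dgrad_{name}"] = g
                row[f"dgrad_se_{name}"] = s
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(GRADIENT_SCHEMA + "\n")
        df.to_csv(fh, index=False)


def read_gradient_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_gradient_table`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if first != GRADIENT_SCHEMA:
            raise ValueError(f"unexpected schema header {first!r}")
        return pd.read_csv(fh)
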