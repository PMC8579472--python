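"""Trust-radius Newton-Raphson minimisation in mathematical coordinates.

Each iteration builds the local quadratic model m(p) = L + g.p + p^T H p / 2
from the callback's gradient and (Gauss-Newton) Hessian, solves the
trust-region subproblem by the dogleg method (with Levenberg-Marquardt
damping when H is not positive definite), and adapts the radius from the
ratio of actual to predicted reduction.

The objective of a simulation-based fit is stochastic: re-simulation noise
puts a floor under resolvable objective changes.  Steps whose |actual
reduction| falls below that floor are accepted but *flagged*; three
consecutive flagged steps terminate the run as noise-dominated.  The
returned solution is always the best-by-objective evaluated point, not the
last iterate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObjectiveEval:
    """What the objective callback must return at a point k."""

    value: float
    gradient: np.ndarray
    hessian: np.ndarray
    noise_floor: float = 0.0


@dataclass(frozen=True)
class TrustConfig:
    """Trust-region hyperparameters (radii in k-space Euclidean norm)."""

    initial_radius: float = 0.3
    shrink: float = 0.5
    expand: float = 1.5
    ratio_low: float = 0.25
    ratio_high: float = 0.75
    max_iterations: int = 30
    objective_tol: float = 1e-10
    gradient_tol: float = 1e-10
    min_radius: float = 1e-8
    noise_multiplier: float = 1.0
    max_flagged: int = 3

    def __post_init__(self):
        if not (0 < self.shrink < 1 < self.expand):
            raise ValueError("require 0 < shrink < 1 < expand")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    k: np.ndarray
    value: float
    radius: float
    step_norm: float
    accepted: bool
    flagged: bool


@dataclass
class OptimizationTrace:
    """Per-iteration history plus the best-by-objective iterate."""

    records: list[IterationRecord] = field(default_factory=list)
    best_index: int = 0
    reason: str = ""
    n_accepted: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> IterationRecord:
        return self.records[self.best_index]

    @property
    def best_k(self) -> np.ndarray:
        return self.best.k

    @property
    def best_value(self) -> float:
        return self.best.value

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reason": self.reason, "best_index": self.best_index,
            "n_accepted": self.n_accepted, "warnings": self.warnings,
            "iterations": [
                {"k": r.k.tolist(), "value": r.value, "radius": r.radius,
                 "step_norm": r.step_norm, "accepted": r.accepted,
                 "flagged": r.flagged} for r in self.records],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _damped_newton(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Newton step -H^-1 g, LM-damping H until positive definite."""
    n = H.shape[0]
    scale = float(np.max(np.abs(np.diag(H)))) or 1.0
    nu = 0.0
    for _ in range(40):
        try:
            c = np.linalg.cholesky(H + nu * np.eye(n))
            y = np.linalg.solve(c, -g)
            return np.linalg.solve(c.T, y)
        except np.linalg.LinAlgError:
            nu = max(2.0 * nu, 1e-10 * scale)
    raise np.linalg.LinAlgError("could not damp Hessian to positive definite")


def dogleg_step(g: np.ndarray, H: np.ndarray, radius: float) -> np.ndarray:
    """Dogleg solution of min m(p) subject to ||p|| <= radius."""
    p_newton = _damped_newton(H, g)
    if np.linalg.norm(p_newton) <= radius:
        return p_newton
    gHg = float(g @ H @ g)
    gnorm = float(np.linalg.norm(g))
    if gHg <= 0:
        return -(radius / gnorm) * g
    p_cauchy = -(gnorm ** 2 / gHg) * g
    pc_norm = float(np.linalg.norm(p_cauchy))
    if pc_norm >= radius:
        return -(radius / gnorm) * g
    # walk from the Cauchy point towards the Newton point to the boundary
    d = p_newton - p_cauchy
    a = float(d @ d)
    b = 2.0 * float(p_cauchy @ d)
    c = pc_norm ** 2 - radius ** 2
    tau = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return p_cauchy + tau * d


def optimize(objective: Callable[[np.ndarray], ObjectiveEval],
             k0: np.ndarray, config: TrustConfig = TrustConfig(),
             overfit_threshold: float = 3.0) -> OptimizationTrace:
    """Minimise a noisy objective by trust-radius Newton-Raphson.

    ``objective`` maps a k-vector to an :class:`ObjectiveEval`.  Any
    evaluated point whose |k_i| exceeds ``overfit_threshold`` prior widths
    adds an over-fitting warning to the trace (parameters far from the
    prior centre are suspect), without rejecting the step.
    """
    k = np.atleast_1d(np.asarray(k0, float)).copy()
    if not np.all(np.isfinite(k)):
        raise ValueError("k0 must be finite")
    cur = objective(k)
    if not np.isfinite(cur.value):
        raise ValueError("objective is non-finite at k0")
    trace = OptimizationTrace()
    radius = config.initial_radius
    trace.records.append(IterationRecord(k.copy(), cur.value, radius, 0.0,
                                         True, False))
    _check_overfit(k, overfit_threshold, trace)
    consecutive_flagged = 0

    for it in range(config.max_iterations):
        g, H = cur.gradient, cur.hessian
        if float(np.linalg.norm(g)) < config.gradient_tol:
            trace.reason = "gradient-converged"
            break
        p = dogleg_step(g, H, radius)
        step_norm = float(np.linalg.norm(p))
        pred = -(float(g @ p) + 0.5 * float(p @ H @ p))
        trial_k = k + p
        trial = objective(trial_k)
        ared = cur.value - trial.value
        noise = config.noise_multiplier * max(cur.noise_floor,
                                              trial.noise_floor)
        ratio = ared / pred if pred > 0 else -np.inf

        flagged = abs(ared) <= noise and noise > 0
        accepted = ared > 0 or flagged
        trace.records.append(IterationRecord(trial_k.copy(), trial.value,
                                             radius, step_norm, accepted,
                                             flagged))
        _check_overfit(trial_k, overfit_threshold, trace)
        if trial.value < trace.best_value:
            trace.best_index = len(trace.records) - 1

        if ratio < config.ratio_low:
            radius *= config.shrink
        elif ratio > config.ratio_high and step_norm >= 0.99 * radius:
            radius *= config.expand

        logger.info("iter %d: L=%.6g |step|=%.3g radius=%.3g accepted=%s%s",
                    it + 1, trial.value, step_norm, radius, accepted,
                    " (noise-flagged)" if flagged else "")

        if accepted:
            k, cur = trial_k, trial
            trace.n_accepted += 1
            consecutive_flagged = consecutive_flagged + 1 if flagged else 0
            if consecutive_flagged >= config.max_flagged:
                trace.reason = "noise-dominated"
                break
            if 0 < ared < config.objective_tol and not flagged:
                trace.reason = "objective-converged"
                break
        if radius < config.min_radius:
            trace.reason = "radius-collapsed"
            break
    else:
        trace.reason = "max-iterations"
    if not trace.reason:
        pass
    return trace


def _check_overfit(k: np.ndarray, threshold: float,
                   trace: OptimizationTrace) -> None:
    exceeded = np.flatnonzero(np.abs(k) > threshold)
    for i in exceeded:
        msg = (f"over-fitting warning: |k[{i}]| = {abs(k[i]):.2f} exceeds "
               f"{threshold:g} prior widths")
        if msg not in trace.warnings:
            trace.warnings.append(msg)


def optimize_lbfgs(objective: Callable[[np.ndarray], ObjectiveEval],
                   k0: np.ndarray, max_iterations: int = 200
                   ) -> OptimizationTrace:
    """L-BFGS-B alternative behind the same callback contract (not the
    default; provided for cross-checking on deterministic objectives)."""
    from scipy.optimize import minimize

    trace = OptimizationTrace()

    def fun(k):
        ev = objective(np.asarray(k, float))
        trace.records.append(IterationRecord(np.asarray(k, float).copy(),
                                             ev.value, np.nan, np.nan, True,
                                             False))
        if ev.value < trace.best_value:
            trace.best_index = len(trace.records) - 1
        return ev.value, np.asarray(ev.gradient, float)

    res = minimize(fun, np.asarray(k0, float), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iterations})
    trace.reason = f"lbfgs:{res.message}"
    trace.n_accepted = int(res.nit)
    return trace
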