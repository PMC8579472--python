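"""Regularised least-squares objective over mathematical parameters.

The objective is

    L(k) = sum_m L_m(k) + w_reg * ||k||^2,

with per-molecule target terms

    L_m(k) = sum_a w_a * [ (<dU>_a^CG(k) - <dU>_a^ref) / d ]^2,

a weighted sum of squared differences between the current-model and
reference free-energy gradients, made dimensionless by a normalisation
scale ``d``.  The quadratic penalty is a Gaussian prior centred on the
initial parameters (k = 0); ``w_reg`` defaults to 0.01.

First derivatives chain through the physical mapping K_i = K_i(0) + t_i k_i:
the Jacobian of the residual vector is J[(m,a), i] = t_i * g[(m,a), i] / d
with ``g`` the parameter gradients of <dU>_a, giving

    grad L = 2 J^T (w o r) + 2 w_reg k,
    H      ~ 2 J^T W J + 2 w_reg I        (Gauss-Newton).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alchemy import GradientEstimate, ParamGradientEstimate
from .forcefield import ParameterSpace

DEFAULT_W_REG = 0.01


@dataclass(frozen=True)
class TargetSpec:
    """Reference free-energy gradients for one molecule and stage.

    ``weights`` default to uniform 1/n_alpha; ``d`` defaults to
    max(1 kJ/mol, RMS of the reference means) so residuals are
    dimensionless and of order one.
    """

    molecule: str
    stage: str
    alphas: np.ndarray
    ref_mean: np.ndarray
    ref_se: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    d: float = None             # type: ignore[assignment]

    def __post_init__(self):
        a = np.asarray(self.alphas, float)
        m = np.asarray(self.ref_mean, float)
        s = np.asarray(self.ref_se, float)
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "ref_mean", m)
        object.__setattr__(self, "ref_se", s)
        if not (a.size == m.size == s.size):
            raise ValueError("alpha/mean/se lengths differ")
        if self.weights is None:
            w = np.full(a.size, 1.0 / a.size)
        else:
            w = np.asarray(self.weights, float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)
        if self.d is None:
            rms = float(np.sqrt(np.mean(m ** 2)))
            object.__setattr__(self, "d", max(1.0, rms))
        elif self.d <= 0:
            raise ValueError("normalisation scale d must be positive")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"molecule": self.molecule, "stage": self.stage,
                           "alpha": self.alphas, "dudl_mean": self.ref_mean,
                           "dudl_se": self.ref_se, "weight": self.weights,
                           "d": self.d})
        with open(path, "w") as fh:
            fh.write("# fegrad-target v1\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetSpec":
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "# fegrad-target v1":
                raise ValueError(f"unexpected schema header {header!r}")
            df = pd.read_csv(fh)
        return cls(molecule=str(df["molecule"].iloc[0]),
                   stage=str(df["stage"].iloc[0]),
                   alphas=df["alpha"].to_numpy(),
                   ref_mean=df["dudl_mean"].to_numpy(),
                   ref_se=df["dudl_se"].to_numpy(),
                   weights=df["weight"].to_numpy(),
                   d=float(df["d"].iloc[0]))


def _match_alphas(target: TargetSpec, estimates: list[GradientEstimate]
                  ) -> np.ndarray:
    """Order current-model estimates onto the target's alpha grid."""
    by_alpha = {}
    for e in estimates:
        by_alpha[round(float(e.alpha), 12)] = e
    out = []
    for a in target.alphas:
        key = round(float(a), 12)
        if key not in by_alpha:
            raise ValueError(f"missing current-model estimate at alpha={a:g}")
        out.append(by_alpha[key])
    return out


def evaluate_target(target: TargetSpec, cg_estimates: list[GradientEstimate]
                    ) -> tuple[float, np.ndarray]:
    """Target term L_m and the dimensionless residual vector."""
    est = _match_alphas(target, cg_estimates)
    cg = np.array([e.mean for e in est])
    r = (cg - target.ref_mean) / target.d
    L_m = float(np.sum(target.weights * r ** 2))
    return L_m, r


@dataclass(frozen=True)
class ObjectiveReport:
    """Value, decomposition and derivatives of L(k) at one point."""

    total: float
    per_target: dict[str, float]
    penalty: float
    residuals: np.ndarray
    weights: np.ndarray
    noise_floor: float
    k: np.ndarray
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total": self.total, "per_target": self.per_target,
            "penalty": self.penalty, "noise_floor": self.noise_floor,
            "k": self.k.tolist(), "residuals": self.residuals.tolist(),
            "weights": self.weights.tolist(),
            "gradient": None if self.gradient is None else self.gradient.tolist(),
            "hessian": None if self.hessian is None else self.hessian.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def evaluate_objective(k: np.ndarray, targets: list[TargetSpec],
                       cg_estimates: list[list[GradientEstimate]],
                       w_reg: float = DEFAULT_W_REG) -> ObjectiveReport:
    """Assemble L(k) = sum_m L_m + w_reg ||k||^2 with its noise floor.

    The noise floor is the expected contribution of the reference SEs to
    the objective, sum_m sum_a w_a (SE_a / d)^2; an optimiser cannot
    meaningfully resolve objective changes below it.
    """
    if w_reg < 0:
        raise ValueError("w_reg must be non-negative")
    k = np.atleast_1d(np.asarray(k, float))
    per_target: dict[str, float] = {}
    residuals, weights = [], []
    noise = 0.0
    for target, est in zip(targets, cg_estimates):
        L_m, r = evaluate_target(target, est)
        per_target[f"{target.molecule}/{target.stage}"] = L_m
        residuals.append(r)
        weights.append(target.weights)
        noise += float(np.sum(target.weights * (target.ref_se / target.d) ** 2))
    penalty = float(w_reg * np.sum(k ** 2))
    total = sum(per_target.values()) + penalty
    return ObjectiveReport(
        total=total, per_target=per_target, penalty=penalty,
        residuals=np.concatenate(residuals) if residuals else np.empty(0),
        weights=np.concatenate(weights) if weights else np.empty(0),
        noise_floor=noise, k=k.copy())


def objective_derivatives(k: np.ndarray, targets: list[TargetSpec],
                          space: ParameterSpace,
                          cg_estimates: list[list[GradientEstimate]],
                          param_grads: list[list[ParamGradientEstimate]],
                          w_reg: float = DEFAULT_W_REG) -> ObjectiveReport:
    """Objective with analytic gradient and Gauss-Newton Hessian.

    ``param_grads[m][j]`` holds d<dU>_a/dK at the j-th alpha of target m,
    computed at the current parameters.
    """
    report = evaluate_objective(k, targets, cg_estimates, w_reg)
    k = report.k
    n_free = space.n_free
    t_free = space.t[space.free_indices]
    rows = []
    for target, grads in zip(targets, param_grads):
        by_alpha = {round(float(g.alpha), 12): g for g in grads}
        for a in target.alphas:
            key = round(float(a), 12)
            if key not in by_alpha:
                raise ValueError(f"missing parameter gradients at alpha={a:g}")
            g = by_alpha[key]
            if g.grad.size != n_free:
                raise ValueError("parameter-gradient width does not match "
                                 "the unfrozen parameter count")
            rows.append(t_free * g.grad / target.d)
    J = np.array(rows) if rows else np.empty((0, n_free))
    r, w = report.residuals, report.weights
    grad = 2.0 * J.T @ (w * r) + 2.0 * w_reg * k
    H = 2.0 * (J.T * w) @ J + 2.0 * w_reg * np.eye(n_free)
    H = 0.5 * (H + H.T)
    return ObjectiveReport(
        total=report.total, per_target=report.per_target,
        penalty=report.penalty, residuals=r, weights=w,
        noise_floor=report.noise_floor, k=k, gradient=grad, hessian=H)
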