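"""Regularised least-squares objective: values, derivatives, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fegrad.alchemy import GradientEstimate, ParamGradientEstimate
from fegrad.forcefield import ParameterSpace
from fegrad.objective import (TargetSpec, evaluate_objective, evaluate_target,
                              objective_derivatives)


def target(alphas, means, ses=None, **kw):
    alphas = np.asarray(alphas, float)
    means = np.asarray(means, float)
    ses = np.zeros_like(means) if ses is None else np.asarray(ses, float)
    return TargetSpec("mol", "vdw", alphas, means, ses, **kw)


def estimates(alphas, means, ses=None):
    ses = np.zeros_like(np.asarray(means, float)) if ses is None else ses
    return [GradientEstimate(a, m, s, 10)
            for a, m, s in zip(alphas, means, ses)]


class TestTargetTerm:
    def test_perfect_fit_is_zero(self):
        t = target([0.2, 1.0], [-3.0, -8.0])
        L, r = evaluate_target(t, estimates([0.2, 1.0], [-3.0, -8.0]))
        assert L == 0.0
        assert np.all(r == 0.0)

    def test_single_point_arithmetic(self):
        t = target([0.5], [1.0], d=1.0)
        L, _ = evaluate_target(t, estimates([0.5], [3.0]))
        assert L == pytest.approx(4.0)

    def test_two_point_mean_square(self):
        t = target([0.2, 0.8], [0.0, 0.0], d=1.0)
        L, _ = evaluate_target(t, estimates([0.2, 0.8], [1.0, -1.0]))
        assert L == pytest.approx(1.0)

    def test_missing_alpha_point_raises(self):
        t = target([0.2, 0.8], [0.0, 0.0])
        with pytest.raises(ValueError, match="missing"):
            evaluate_target(t, estimates([0.2], [0.0]))

    def test_doubling_d_quarters_the_term(self):
        t1 = target([0.5], [0.0], d=2.0)
        t2 = target([0.5], [0.0], d=4.0)
        e = estimates([0.5], [1.0])
        assert evaluate_target(t2, e)[0] == pytest.approx(
            evaluate_target(t1, e)[0] / 4)

    def test_default_normalisation_floor(self):
        assert target([0.5], [0.1]).d == 1.0
        assert target([0.5], [-20.0]).d == pytest.approx(20.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            target([0.2, 0.8], [0.0, 0.0], weights=np.array([0.5, 0.6]))


class TestObjective:
    def test_perfect_fit_at_origin(self):
        t = target([0.5], [2.0])
        rep = evaluate_objective(np.zeros(1), [t],
                                 [estimates([0.5], [2.0])])
        assert rep.total == 0.0

    def test_penalty_arithmetic_with_default_w_reg(self):
        """Perfect fit at k = (1, 1) leaves only the prior penalty
        w_reg * ||k||^2 = 0.01 * 2 = 0.02."""
        t = target([0.5], [2.0])
        rep = evaluate_objective(np.ones(2), [t], [estimates([0.5], [2.0])])
        assert rep.total == pytest.approx(0.02)

    def test_zero_w_reg_disables_penalty(self):
        t = target([0.5], [0.0], d=1.0)
        rep = evaluate_objective(np.ones(3), [t],
                                 [estimates([0.5], [2.0])], w_reg=0.0)
        assert rep.total == pytest.approx(4.0)
        assert rep.penalty == 0.0

    def test_total_decomposes_exactly(self):
        t1 = target([0.2, 0.8], [1.0, 2.0], d=1.0)
        t2 = TargetSpec("other", "elec", np.array([0.5]), np.array([0.0]),
                        np.array([0.0]), d=1.0)
        k = np.array([0.3, -0.2])
        rep = evaluate_objective(
            k, [t1, t2],
            [estimates([0.2, 0.8], [1.5, 1.5]), estimates([0.5], [1.0])])
        assert rep.total == pytest.approx(
            sum(rep.per_target.values()) + rep.penalty, abs=1e-12)

    def test_invariant_under_target_reordering(self):
        t1 = target([0.2, 0.8], [1.0, 2.0])
        t2 = TargetSpec("b", "elec", np.array([0.5]), np.array([3.0]),
                        np.array([0.0]))
        e1 = estimates([0.2, 0.8], [1.4, 2.2])
        e2 = estimates([0.5], [2.5])
        k = np.array([0.1])
        a = evaluate_objective(k, [t1, t2], [e1, e2]).total
        b = evaluate_objective(k, [t2, t1], [e2, e1]).total
        assert a == pytest.approx(b, abs=1e-14)

    def test_noise_floor_formula(self):
        t = target([0.2, 0.8], [0.0, 0.0], ses=[0.5, 0.3], d=2.0)
        rep = evaluate_objective(np.zeros(1), [t],
                                 [estimates([0.2, 0.8], [0.0, 0.0])])
        expected = 0.5 * (0.5 / 2) ** 2 + 0.5 * (0.3 / 2) ** 2
        assert rep.noise_floor == pytest.approx(expected)

    def test_negative_w_reg_rejected(self):
        with pytest.raises(ValueError):
            evaluate_objective(np.zeros(1), [], [], w_reg=-0.1)


class TestDerivatives:
    def space(self):
        return ParameterSpace.create(("s.epsilon",), ("epsilon",), (2.0,),
                                     t=(0.5,))

    def test_stationary_at_perfect_fit(self):
        t = target([0.5], [2.0])
        pg = [ParamGradientEstimate(0.5, np.array([1.7]), np.array([0.0]),
                                    np.array([1e-4]), ("s.epsilon",))]
        rep = objective_derivatives(np.zeros(1), [t], self.space(),
                                    [estimates([0.5], [2.0])], [pg])
        assert np.allclose(rep.gradient, 0.0)

    def test_pure_penalty_derivatives(self):
        """With zero-weight targets the derivatives reduce to the prior:
        grad = 2 w_reg k, H = 2 w_reg I."""
        t = target([0.5], [0.0], weights=np.array([1.0]), d=1.0)
        pg = [ParamGradientEstimate(0.5, np.array([0.0]), np.array([0.0]),
                                    np.array([1e-4]), ("s.epsilon",))]
        k = np.array([1.5])
        rep = objective_derivatives(k, [t], self.space(),
                                    [estimates([0.5], [0.0])], [pg],
                                    w_reg=0.01)
        assert rep.gradient[0] == pytest.approx(2 * 0.01 * 1.5)
        assert rep.hessian[0, 0] == pytest.approx(2 * 0.01)

    def test_gradient_matches_finite_difference_of_objective(self):
        """Frozen linear surrogate: <dU>(k) = m0 + g t k, so the analytic
        chain-rule gradient must match central differences of the
        objective itself to high accuracy."""
        space = self.space()
        g_phys = -2.4           # d<dU>/dK, held fixed (frozen snapshots)
        m0, ref = -5.0, -6.0
        t_spec = target([0.5], [ref], d=3.0)

        def cg_at(k):
            K = space.map_to_physical(k)
            return estimates([0.5], [m0 + g_phys * (K[0] - space.K0[0])])

        k = np.array([0.7])
        pg = [ParamGradientEstimate(0.5, np.array([g_phys]),
                                    np.array([0.0]), np.array([1e-4]),
                                    ("s.epsilon",))]
        rep = objective_derivatives(k, [t_spec], space, [cg_at(k)], [pg])
        h = 1e-6
        num = (evaluate_objective(k + h, [t_spec], [cg_at(k + h)]).total
               - evaluate_objective(k - h, [t_spec], [cg_at(k - h)]).total
               ) / (2 * h)
        assert rep.gradient[0] == pytest.approx(num, rel=1e-6)

    @given(hnp.arrays(np.float64, (4, 2),
                      elements=st.floats(-5, 5, allow_nan=False)))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_gauss_newton_hessian_positive_semidefinite(self, J):
        w = np.full(4, 0.25)
        H = 2.0 * (J.T * w) @ J + 2.0 * 0.01 * np.eye(2)
        eig = np.linalg.eigvalsh(H)
        assert np.all(eig >= -1e-10)

    def test_dimension_mismatch_raises(self):
        t = target([0.5], [0.0])
        pg = [ParamGradientEstimate(0.5, np.array([1.0, 2.0]),
                                    np.zeros(2), np.full(2, 1e-4),
                                    ("a", "b"))]
        with pytest.raises(ValueError, match="width"):
            objective_derivatives(np.zeros(1), [t], self.space(),
                                  [estimates([0.5], [0.0])], [pg])
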