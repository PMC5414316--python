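"""Leave-one-out strategies against the worked example and the naive oracle."""

import dataclasses

import numpy as np
import numpy.testing as npt
import pytest

from gblupcv import (
    DegenerateLeverageError,
    GenotypeMatrix,
    PhenotypeVector,
    UndefinedStatisticError,
    VarianceComponents,
    build_design_mem,
    build_q,
    leverage_bvm,
    leverage_mem,
    loocv_bvm_strategy1,
    loocv_bvm_strategy2,
    loocv_mem,
    naive_loocv,
    solve_mem,
    summarize,
)
from conftest import random_instance, xxt_nonsingular

TOY_LEVERAGES = [0.46, 0.51, 0.55]
TOY_RESIDUALS = [1.13, 1.21, -2.66]


class TestLeverage:
    def test_toy_mem(self, toy):
        g, _, vc = toy
        npt.assert_array_equal(np.round(leverage_mem(g, vc).values, 2), TOY_LEVERAGES)

    def test_toy_bvm(self, toy):
        g, _, vc = toy
        npt.assert_array_equal(np.round(leverage_bvm(g, vc).values, 2), TOY_LEVERAGES)

    def test_extreme_shrinkage_tends_to_1_over_n(self, toy):
        g, _, _ = toy
        vc = VarianceComponents.from_lambda(1e12)
        npt.assert_allclose(leverage_mem(g, vc).values, 1 / 3, rtol=1e-6)

    def test_matches_dense_hat_matrix(self):
        # dense oracle: explicitly form H = X* A^-1 X*'
        rng = np.random.default_rng(11)
        g, y, vc = random_instance(rng, n=6, p=4)
        Xs = build_design_mem(g)
        A = Xs.T @ Xs + np.diag([0] + [1] * 4) * vc.lambda_ratio
        H = Xs @ np.linalg.inv(A) @ Xs.T
        npt.assert_allclose(leverage_mem(g, vc).values, np.diag(H), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_bvm_equals_mem_leverage(self, seed):
        rng = np.random.default_rng(seed)
        g, _, vc = random_instance(rng, n=4, p=9)
        if not xxt_nonsingular(g):
            pytest.skip("rank-deficient draw")
        npt.assert_allclose(leverage_bvm(g, vc).values,
                            leverage_mem(g, vc).values, atol=1e-8)

    def test_minimal_n2_in_unit_interval(self):
        g = GenotypeMatrix.from_array([[0, 2], [2, 1]])
        vc = VarianceComponents.from_lambda(10)
        for lev in (leverage_mem(g, vc).values, leverage_bvm(g, vc).values):
            assert np.all((lev > 0) & (lev < 1))


class TestEfficientStrategies:
    def test_toy_residuals_all_strategies(self, toy):
        g, y, vc = toy
        for result in (loocv_mem(g, y, vc),
                       loocv_bvm_strategy1(g, y, vc),
                       naive_loocv(g, y, vc, "MEM"),
                       naive_loocv(g, y, vc, "BVM")):
            npt.assert_array_equal(np.round(result.residuals, 2), TOY_RESIDUALS)
        # strategy II is a BLP approximation at sigma2_L=1000: close, not equal
        r2 = loocv_bvm_strategy2(build_q(g, y, vc), y)
        npt.assert_allclose(r2.residuals, TOY_RESIDUALS, atol=0.01)

    def test_toy_strategy2_tight_at_large_sigma_l(self, toy):
        g, y, vc = toy
        vc7 = dataclasses.replace(vc, sigma2_L=1e7)
        r2 = loocv_bvm_strategy2(build_q(g, y, vc7), y)
        npt.assert_array_equal(np.round(r2.residuals, 2), TOY_RESIDUALS)

    @pytest.mark.parametrize("seed", range(8))
    def test_mem_equals_naive(self, seed):
        rng = np.random.default_rng(100 + seed)
        g, y, vc = random_instance(rng)
        npt.assert_allclose(loocv_mem(g, y, vc).residuals,
                            naive_loocv(g, y, vc, "MEM").residuals, rtol=1e-8, atol=1e-10)

    def test_identical_rows_constant_y(self):
        # every training set looks the same, so every prediction is equal
        g = GenotypeMatrix.from_array(np.tile([1, 2, 0], (4, 1)))
        y = PhenotypeVector(np.full(4, 2.5), g.individual_ids)
        vc = VarianceComponents.from_lambda(10)
        eff = loocv_mem(g, y, vc)
        naive = naive_loocv(g, y, vc, "MEM")
        npt.assert_allclose(eff.residuals, naive.residuals, atol=1e-10)
        assert np.ptp(eff.predictions) < 1e-10

    def test_interpolation_limit_small_lambda(self, toy):
        # feed the model its own fitted values: as shrinkage vanishes the
        # smoother approaches a projection, so refitting reproduces them
        # and the unscaled prediction residual of every record tends to 0
        g, y, _ = toy
        scale = {}
        for lam in (1.0, 1e-2, 1e-4):
            vcl = VarianceComponents.from_lambda(lam)
            fit = build_design_mem(g) @ solve_mem(g, y, vcl).solution_vector
            yf = PhenotypeVector(fit, g.individual_ids)
            refit = build_design_mem(g) @ solve_mem(g, yf, vcl).solution_vector
            scale[lam] = np.abs(yf.values - refit).max()
        assert scale[1e-4] < scale[1e-2] < scale[1.0]
        assert scale[1e-4] < 1e-3


class TestStrategyII:
    def test_toy_q_matrix_block(self, toy):
        g, y, vc = toy
        qm = build_q(g, y, vc)
        npt.assert_allclose(np.diag(qm.v_star), [1002.40, 1001.70, 1001.90])
        npt.assert_allclose([qm.v_star[0, 1], qm.v_star[0, 2], qm.v_star[1, 2]],
                            [1000.80, 1000.80, 1000.30])
        npt.assert_array_equal(qm.q[0, 1:], y.values)
        npt.assert_array_equal(qm.q, qm.q.T)

    def test_q_inverse_contract(self, toy):
        g, y, vc = toy
        qm = build_q(g, y, vc)
        npt.assert_allclose(qm.q_inv @ qm.q, np.eye(4), atol=1e-6)

    def test_pev_independent_of_phenotypes(self, toy):
        g, y, vc = toy
        r_a = loocv_bvm_strategy2(build_q(g, y, vc), y)
        y_b = PhenotypeVector(y.values + 3.7, g.individual_ids)
        r_b = loocv_bvm_strategy2(build_q(g, y_b, vc), y_b)
        y_c = PhenotypeVector([5.0, -1.0, 0.25], g.individual_ids)
        r_c = loocv_bvm_strategy2(build_q(g, y_c, vc), y_c)
        npt.assert_allclose(r_a.pev, r_b.pev, atol=1e-8)
        npt.assert_allclose(r_a.pev, r_c.pev, atol=1e-8)

    def test_pev_matches_conditional_variance_oracle(self, toy):
        # independent route: PEV_j = V*_jj - V*_{j,-j} V*_{-j,-j}^-1 V*_{-j,j}
        g, y, vc = toy
        qm = build_q(g, y, vc)
        r = loocv_bvm_strategy2(qm, y)
        V = qm.v_star
        for j in range(3):
            keep = [k for k in range(3) if k != j]
            schur = V[j, j] - V[j, keep] @ np.linalg.solve(V[np.ix_(keep, keep)], V[keep, j])
            npt.assert_allclose(r.pev[j], schur, rtol=1e-6)

    def test_reliability_in_unit_interval(self, toy):
        g, y, vc = toy
        r = loocv_bvm_strategy2(build_q(g, y, vc), y)
        assert np.all((r.reliability > 0) & (r.reliability < 1))

    @pytest.mark.parametrize("sigma_l,tol", [(1e3, 1e-3), (1e7, 1e-6)])
    def test_converges_to_strategy1(self, sigma_l, tol):
        rng = np.random.default_rng(21)
        g, y, vc = random_instance(rng, n=5, p=12)
        if not xxt_nonsingular(g):
            pytest.skip("rank-deficient draw")
        vcl = dataclasses.replace(vc, sigma2_L=sigma_l)
        r1 = loocv_bvm_strategy1(g, y, vcl)
        r2 = loocv_bvm_strategy2(build_q(g, y, vcl), y)
        scale = np.abs(r1.residuals).max()
        npt.assert_allclose(r2.residuals, r1.residuals, atol=tol * scale)


class TestNaive:
    def test_n2_uses_exactly_the_other_record(self):
        g = GenotypeMatrix.from_array([[0, 1], [2, 0]])
        y = PhenotypeVector([1.0, 3.0], g.individual_ids)
        vc = VarianceComponents.from_lambda(5)
        r = naive_loocv(g, y, vc, "MEM")
        # refit on one record: direct 3x3 ridge solve per left-out j
        Xs = build_design_mem(g)
        for j, k in ((0, 1), (1, 0)):
            A = np.outer(Xs[k], Xs[k]) + np.diag([0, 1, 1]) * vc.lambda_ratio
            b = np.linalg.solve(A, Xs[k] * y.values[k])
            npt.assert_allclose(r.residuals[j], y.values[j] - Xs[j] @ b, rtol=1e-10)

    def test_indices_subset_spot_check(self, toy):
        g, y, vc = toy
        r = naive_loocv(g, y, vc, "MEM", indices=[2])
        assert np.isnan(r.residuals[:2]).all()
        npt.assert_allclose(r.residuals[2], -2.656, atol=5e-4)
        assert r.press == pytest.approx(r.residuals[2] ** 2)


class TestSummarize:
    def test_toy_press(self, toy):
        g, y, vc = toy
        r = loocv_mem(g, y, vc)
        npt.assert_allclose(r.press, np.sum(r.residuals**2))
        # 2-decimal arithmetic on the printed residuals gives the same ballpark
        assert r.press == pytest.approx(1.13**2 + 1.21**2 + 2.66**2, abs=0.05)

    def test_perfect_pair_accuracy_one(self):
        press, acc = summarize(np.zeros(2), np.array([1.0, 2.0]))
        assert press == 0.0
        assert acc == pytest.approx(1.0)

    def test_press_permutation_invariant(self):
        rng = np.random.default_rng(9)
        e = rng.standard_normal(10)
        y = rng.standard_normal(10)
        perm = rng.permutation(10)
        p1, _ = summarize(e, y)
        p2, _ = summarize(e[perm], y[perm])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_single_individual_mask_rejected(self, toy):
        g, y, vc = toy
        r = loocv_mem(g, y, vc)
        with pytest.raises(UndefinedStatisticError, match="at least 2"):
            summarize(r.residuals, y.values, mask=[0])

    def test_constant_prediction_rejected(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedStatisticError, match="constant"):
            summarize(y - 5.0, y)  # predictions all equal 5

    def test_subgroup_mask_restricts_aggregates(self, toy):
        g, y, vc = toy
        full = loocv_mem(g, y, vc)
        sub = loocv_mem(g, y, vc, mask=[0, 2])
        npt.assert_array_equal(sub.residuals, full.residuals)
        assert sub.press == pytest.approx(full.residuals[0] ** 2 + full.residuals[2] ** 2)


class TestDegenerate:
    def test_leverage_one_raises(self):
        with pytest.raises(DegenerateLeverageError, match="undefined"):
            from gblupcv.loocv import LeverageVector
            LeverageVector(values=np.array([0.5, 1.0 - 1e-15]), source="MEM-H")
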