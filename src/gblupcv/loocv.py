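"""Exact leave-one-out cross-validation (LOOCV) for genomic BLUP.

Naively, LOOCV refits the model n times. Because ridge-BLUP is a linear
smoother, every leave-one-out residual is available in closed form from a
single full-data fit; three equivalent efficient routes are implemented,
plus the naive refitting oracle they are all tested against.

* ``loocv_mem`` — hat-matrix identity for the marker-effect model:
  e_hat_j = (y_j - x*_j' b_hat) / (1 - H_jj), with H_jj the j-th diagonal
  of H = X*(X*'X* + D lambda)^-1 X*'. Cost: one order-(p+1) solve.

* ``loocv_bvm_strategy1`` — same identity through the breeding-value
  model, with C_jj the diagonal of C = Z*(Z*'Z* + G lambda)^-1 Z*'.
  Cost: one order-(n+1) solve; preferred when p >= n.

* ``loocv_bvm_strategy2`` — augmented-matrix route. The covariance of y
  (overall mean treated as random with a large variance sigma2_L, so
  var(y) = V* = X* Sigma X*' + I sigma2_e) is bordered with y'y and y'
  into Q; a single inversion of Q yields every residual by a 2x2
  partitioned-inverse identity, and the prediction error variance (PEV)
  and reliability of every individual as a by-product.

* ``naive_loocv`` — literal n-fold refitting; the reference oracle.

PRESS (sum of squared leave-out residuals) and predictive accuracy (the
Pearson correlation of observed and predicted phenotypes) can be computed
over all individuals or over any subgroup (e.g. terminal offspring only)
via a mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.linalg

from .exceptions import (
    DataError,
    DegenerateLeverageError,
    DegeneratePredictionError,
    NumericalRankError,
    UndefinedStatisticError,
)
from .models import build_design_mem, fitted_values, solve_bvm, solve_mem, spd_inverse
from .types import GenotypeMatrix, MixedModelSolution, PhenotypeVector, VarianceComponents

__all__ = [
    "LeverageVector",
    "QMatrix",
    "LoocvResult",
    "leverage_mem",
    "leverage_bvm",
    "loocv_mem",
    "loocv_bvm_strategy1",
    "build_q",
    "loocv_bvm_strategy2",
    "naive_loocv",
    "summarize",
]

# leverage within 1e-12 of 1 means the left-out prediction is undefined
_LEVERAGE_TOL = 1e-12


@dataclass(frozen=True)
class LeverageVector:
    """Diagonal of the hat-type matrix (H for MEM, C for BVM).

    Each entry is strictly inside (0, 1) when lambda > 0; the value
    governs how much the full-data residual is inflated to obtain the
    leave-one-out residual.
    """

    values: np.ndarray
    source: Literal["MEM-H", "BVM-C"]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if np.any(v >= 1.0 - _LEVERAGE_TOL):
            j = int(np.argmax(v))
            raise DegenerateLeverageError(
                f"leverage[{j}] = {v[j]:.15g} is numerically 1: observation {j} "
                "predicts itself and its leave-one-out residual is undefined"
            )
        if np.any(v <= 0.0):
            j = int(np.argmin(v))
            raise DegenerateLeverageError(
                f"leverage[{j}] = {v[j]:.15g} is not positive; coefficient matrix "
                "is numerically unsound"
            )
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class QMatrix:
    """The (n+1) x (n+1) bordered covariance matrix of strategy II.

    q[0, 0] = y'y, q[0, 1:] = y', lower-right block = V* = X* Sigma X*'
    + I sigma2_e with Sigma = diag(sigma2_L, sigma2_beta I). ``q_inv`` is
    its inverse, computed once; all leave-one-out quantities are O(1)
    reads from it.
    """

    q: np.ndarray
    q_inv: np.ndarray = field(repr=False)
    sigma2_L_used: float

    @property
    def n_individuals(self) -> int:
        return self.q.shape[0] - 1

    @property
    def v_star(self) -> np.ndarray:
        """The phenotypic covariance block V* (view into q)."""
        return self.q[1:, 1:]


@dataclass(frozen=True)
class LoocvResult:
    """Per-individual LOOCV output plus aggregate PRESS and accuracy.

    predictions = observations - residuals elementwise (exactly).
    ``pev`` and ``reliability`` are filled by strategy II only; the other
    strategies report the leverage vector instead. ``subgroup_mask`` is
    the boolean mask over which press/accuracy were aggregated (all True
    unless a subgroup was requested).
    """

    residuals: np.ndarray
    predictions: np.ndarray
    press: float
    accuracy: float
    strategy: Literal["mem", "bvm1", "bvm2", "naive-mem", "naive-bvm"]
    leverage: Optional[LeverageVector] = None
    pev: Optional[np.ndarray] = None
    reliability: Optional[np.ndarray] = None
    subgroup_mask: Optional[np.ndarray] = None


def _normalize_mask(mask, n: int) -> np.ndarray:
    """Accept a boolean mask, an index sequence or None; return bool mask."""
    if mask is None:
        return np.ones(n, dtype=bool)
    m = np.asarray(mask)
    if m.dtype == bool:
        if m.shape != (n,):
            raise DataError(f"boolean mask has shape {m.shape}, expected ({n},)")
        return m.copy()
    idx = m.astype(int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise DataError(f"mask indices out of range 0..{n - 1}")
    out = np.zeros(n, dtype=bool)
    out[idx] = True
    return out


def summarize(residuals: np.ndarray, y: np.ndarray,
              mask=None) -> tuple[float, float]:
    """PRESS and predictive accuracy over ``mask``.

    press    = sum of squared leave-one-out residuals in the mask.
    accuracy = Pearson correlation of (y_j, y_hat_j) over the mask, where
               y_hat_j = y_j - e_hat_j.

    Raises UndefinedStatisticError if the mask holds fewer than two
    individuals or either vector is constant over it.
    """
    residuals = np.asarray(residuals, float)
    y = np.asarray(y, float)
    m = _normalize_mask(mask, y.size)
    e = residuals[m]
    press = float(np.sum(e**2))
    if m.sum() < 2:
        raise UndefinedStatisticError(
            f"accuracy needs at least 2 individuals in the mask, got {int(m.sum())}"
        )
    yo = y[m]
    yp = yo - e
    if np.ptp(yo) == 0 or np.ptp(yp) == 0:
        raise UndefinedStatisticError(
            "accuracy undefined: observed or predicted phenotypes are constant over the mask"
        )
    accuracy = float(np.corrcoef(yo, yp)[0, 1])
    return press, accuracy


def _finalize(residuals, y, strategy, mask=None, leverage=None,
              pev=None, reliability=None) -> LoocvResult:
    m = _normalize_mask(mask, y.size)
    try:
        press, accuracy = summarize(residuals, y, m)
    except UndefinedStatisticError as err:
        press = float(np.sum(residuals[m] ** 2))
        accuracy = float("nan")
        warnings.warn(f"accuracy unavailable: {err}", stacklevel=3)
    return LoocvResult(
        residuals=residuals, predictions=y - residuals, press=press,
        accuracy=accuracy, strategy=strategy, leverage=leverage,
        pev=pev, reliability=reliability, subgroup_mask=m,
    )


# ---------------------------------------------------------------------------
# MEM route

def leverage_mem(g: GenotypeMatrix, vc: VarianceComponents,
                 solution: MixedModelSolution | None = None) -> LeverageVector:
    """Diagonal of H = X*(X*'X* + D lambda)^-1 X*'.

    Pass a precomputed MEM ``solution`` to reuse its coefficient inverse.
    """
    if solution is None:
        ph = PhenotypeVector(np.zeros(g.n_individuals), g.individual_ids)
        solution = solve_mem(g, ph, vc)
    elif solution.model_kind != "MEM":
        raise DataError("leverage_mem needs a MEM solution")
    Xs = build_design_mem(g)
    h = np.einsum("ij,ij->i", Xs @ solution.coefficient_inverse, Xs)
    return LeverageVector(values=h, source="MEM-H")


def loocv_mem(g: GenotypeMatrix, y: PhenotypeVector, vc: VarianceComponents,
              mask=None) -> LoocvResult:
    """All n leave-one-out residuals from one marker-effect-model fit.

    e_hat_j = (y_j - x*_j' b_hat) / (1 - H_jj), using the full-data BLUP
    b_hat; identical to refitting without record j.
    """
    sol = solve_mem(g, y, vc)
    lev = leverage_mem(g, vc, solution=sol)
    resid = (y.values - fitted_values(g, sol)) / (1.0 - lev.values)
    return _finalize(resid, y.values, "mem", mask, leverage=lev)


# ---------------------------------------------------------------------------
# BVM strategy I

def leverage_bvm(g: GenotypeMatrix, vc: VarianceComponents,
                 solution: MixedModelSolution | None = None) -> LeverageVector:
    """Diagonal of C = Z*(Z*'Z* + G lambda)^-1 Z*'.

    Numerically equal to the MEM leverages (model equivalence); requires
    XX' nonsingular.
    """
    if solution is None:
        ph = PhenotypeVector(np.zeros(g.n_individuals), g.individual_ids)
        solution = solve_bvm(g, ph, vc)
    elif solution.model_kind != "BVM":
        raise DataError("leverage_bvm needs a BVM solution")
    A = solution.coefficient_inverse
    n = g.n_individuals
    j = np.arange(1, n + 1)
    # z*_j = (1, e_j): quadratic form needs only 3 entries of the inverse
    c = A[0, 0] + 2.0 * A[0, j] + A[j, j]
    return LeverageVector(values=c, source="BVM-C")


def loocv_bvm_strategy1(g: GenotypeMatrix, y: PhenotypeVector,
                        vc: VarianceComponents, mask=None) -> LoocvResult:
    """Leave-one-out residuals from one breeding-value-model fit.

    e_hat_j = (y_j - z*_j' u_hat) / (1 - C_jj); agrees with ``loocv_mem``
    by model equivalence but costs an order-(n+1) solve, so it is the
    efficient route when p >= n.
    """
    sol = solve_bvm(g, y, vc)
    lev = leverage_bvm(g, vc, solution=sol)
    resid = (y.values - fitted_values(g, sol)) / (1.0 - lev.values)
    return _finalize(resid, y.values, "bvm1", mask, leverage=lev)


# ---------------------------------------------------------------------------
# BVM strategy II

def build_q(g: GenotypeMatrix, y: PhenotypeVector, vc: VarianceComponents) -> QMatrix:
    """Assemble the bordered covariance matrix Q and invert it once.

    V* = X* Sigma X*' + I sigma2_e = sigma2_L 11' + XX' sigma2_beta
    + I sigma2_e treats the overall mean as a random effect with large
    variance sigma2_L, making the model a pure random-effects (BLP)
    problem. Q borders V* with y'y and y'.
    """
    y.check_aligned(g)
    n = g.n_individuals
    K = g.dosages @ g.dosages.T
    K = 0.5 * (K + K.T)
    v_star = vc.sigma2_L + K * vc.sigma2_beta
    v_star[np.diag_indices_from(v_star)] += vc.sigma2_e
    q = np.empty((n + 1, n + 1))
    q[0, 0] = y.values @ y.values
    q[0, 1:] = y.values
    q[1:, 0] = y.values
    q[1:, 1:] = v_star
    # Q is symmetric but generally indefinite (the y'y border need not
    # dominate), so use a symmetric-indefinite (Bunch-Kaufman) solve
    try:
        q_inv = scipy.linalg.solve(q, np.eye(n + 1), assume_a="sym",
                                   check_finite=False)
    except (scipy.linalg.LinAlgError, ValueError) as err:
        raise NumericalRankError(
            "matrix Q is numerically singular; try a smaller sigma2_L or "
            "check for duplicate phenotype/genotype rows"
        ) from err
    q_inv = 0.5 * (q_inv + q_inv.T)
    return QMatrix(q=q, q_inv=q_inv, sigma2_L_used=vc.sigma2_L)


def loocv_bvm_strategy2(qm: QMatrix, y: PhenotypeVector, mask=None) -> LoocvResult:
    """All leave-one-out residuals, PEVs and reliabilities from Q^-1.

    For individual j, the relevant 2x2 block of the permuted inverse is
    read directly from Q^-1 at rows/columns (0, 1+j) — the permutation is
    pure index selection, never a materialized matrix. Writing that block
    as W11 = [[q^{1,1}, q^{1,1+j}], [q^{1+j,1}, q^{1+j,1+j}]]:

      e_hat_j = -q^{1+j,1} / det(W11)
      PEV_j   = q^{1,1}   / det(W11)   (the (2,2) entry of W11^-1)
      reliability_j = 1 - PEV_j / V*_jj

    PEV equals the conditional variance V*_jj - V*_{j,-j} V*_{-j,-j}^-1
    V*_{-j,j}, so it depends on genotypes and variance components only,
    not on the phenotypes.
    """
    n = qm.n_individuals
    if len(y) != n:
        raise DataError(f"phenotype length {len(y)} does not match Q order {n + 1}")
    Qi = qm.q_inv
    j = np.arange(1, n + 1)
    det = Qi[0, 0] * Qi[j, j] - Qi[0, j] * Qi[j, 0]
    bad = np.abs(det) < 1e-12 * abs(Qi[0, 0])
    if bad.any():
        k = int(np.argmax(bad))
        raise DegeneratePredictionError(
            f"strategy-II residual denominator vanished for individual {k} "
            f"(det = {det[k]:.3g}); Q is too ill-conditioned"
        )
    resid = -Qi[j, 0] / det
    pev = Qi[0, 0] / det
    v_jj = np.diag(qm.v_star)
    reliability = 1.0 - pev / v_jj
    return _finalize(resid, y.values, "bvm2", mask, pev=pev, reliability=reliability)


# ---------------------------------------------------------------------------
# Naive refitting oracle

def naive_loocv(g: GenotypeMatrix, y: PhenotypeVector, vc: VarianceComponents,
                model_kind: Literal["MEM", "BVM"] = "MEM",
                indices: Optional[Sequence[int]] = None,
                mask=None) -> LoocvResult:
    """Literal leave-one-out: refit on n-1 records, predict the held-out one.

    The reference oracle for every efficient strategy. ``indices``
    restricts the (expensive) refits to a subset of individuals for
    spot-checks; positions not refitted carry NaN residuals and are
    excluded from press/accuracy.

    For the BVM the held-out individual is predicted as
    mu_hat + k_j' K_train^-1 u_hat_train with k_j the genomic covariances
    between j and the training set — the standard GBLUP prediction of an
    unphenotyped individual.
    """
    y.check_aligned(g)
    n = g.n_individuals
    which = np.arange(n) if indices is None else np.asarray(indices, dtype=int)
    if which.size and (which.min() < 0 or which.max() >= n):
        raise DataError(f"indices out of range 0..{n - 1}")
    resid = np.full(n, np.nan)
    yv = y.values

    if model_kind == "MEM":
        Xs = build_design_mem(g)
        p = g.n_markers
        for j in which:
            keep = np.ones(n, dtype=bool)
            keep[j] = False
            Xj = Xs[keep]
            A = Xj.T @ Xj
            A[np.arange(1, p + 1), np.arange(1, p + 1)] += vc.lambda_ratio
            try:
                c, low = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
            except scipy.linalg.LinAlgError as err:
                raise NumericalRankError(
                    f"leave-one-out subproblem for individual {j} is singular (MEM)"
                ) from err
            b = scipy.linalg.cho_solve((c, low), Xj.T @ yv[keep], check_finite=False)
            resid[j] = yv[j] - Xs[j] @ b
    elif model_kind == "BVM":
        K = g.dosages @ g.dosages.T
        K = 0.5 * (K + K.T)
        for j in which:
            keep = np.ones(n, dtype=bool)
            keep[j] = False
            Kt = K[np.ix_(keep, keep)]
            try:
                Kt_inv = spd_inverse(Kt, f"XX' with individual {j} removed")
            except NumericalRankError as err:
                raise NumericalRankError(
                    f"leave-one-out subproblem for individual {j} is singular (BVM): {err}"
                ) from err
            m = n - 1
            A = np.empty((m + 1, m + 1))
            A[0, 0] = m
            A[0, 1:] = 1.0
            A[1:, 0] = 1.0
            A[1:, 1:] = Kt_inv * vc.lambda_ratio
            A[np.arange(1, m + 1), np.arange(1, m + 1)] += 1.0
            rhs = np.concatenate([[yv[keep].sum()], yv[keep]])
            sol = np.linalg.solve(A, rhs)
            mu, u = sol[0], sol[1:]
            resid[j] = yv[j] - (mu + K[j, keep] @ (Kt_inv @ u))
    else:
        raise DataError(f"model_kind must be 'MEM' or 'BVM', got {model_kind!r}")

    m = _normalize_mask(mask, n) & ~np.isnan(resid)
    tag = "naive-mem" if model_kind == "MEM" else "naive-bvm"
    return _finalize(resid, yv, tag, m)
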