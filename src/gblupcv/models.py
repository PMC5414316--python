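"""Mixed model equations for ridge-BLUP genomic prediction.

Two equivalent formulations are supported:

* **Marker-effect model (MEM)** — regress phenotypes on all marker dosages
  at once, with iid random marker effects:

      y = 1 mu + X beta + e,   beta_k ~ N(0, sigma2_beta),  e_i ~ N(0, sigma2_e)

  BLUP of (mu, beta) solves ``(X*'X* + D lambda) b = X*'y`` where
  ``X* = [1 X]``, D = diag(0, 1, ..., 1) and lambda = sigma2_e/sigma2_beta.
  System order p+1: preferred when n >= p.

* **Breeding-value model (BVM / GBLUP)** — fit individual breeding values
  u = X beta with var(u) = XX' sigma2_beta:

      y = 1 mu + Z u + e,   Z = I_n

  BLUP solves ``(Z*'Z* + G lambda) v = Z*'y`` with ``Z* = [1 I]`` and
  G = blockdiag(0, (XX')^-1). System order n+1: preferred when p >= n.

The two models give identical predictions of any linear function of the
data (u_hat_j = x_j' beta_hat), which the test suite exploits as a
cross-model oracle.

All coefficient matrices are symmetric positive definite when lambda > 0
(and XX' nonsingular for the BVM), so factorization is by Cholesky; a
failure raises :class:`~gblupcv.exceptions.NumericalRankError` rather than
silently falling back to a pseudo-inverse.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .exceptions import NumericalRankError
from .types import GenotypeMatrix, MixedModelSolution, PhenotypeVector, VarianceComponents

__all__ = [
    "build_design_mem",
    "solve_mem",
    "genomic_covariance",
    "solve_bvm",
    "spd_inverse",
]


def build_design_mem(g: GenotypeMatrix, center: bool = False) -> np.ndarray:
    """Return the MEM design matrix ``X* = [1 X]`` of shape (n, p+1).

    Dosages enter raw (0/1/2) by default; ``center=True`` subtracts the
    column means of X (the intercept column is never touched). Centering
    changes mu_hat's meaning but not leave-one-out residuals.
    """
    X = g.dosages
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    return np.hstack([np.ones((g.n_individuals, 1)), X])


def spd_inverse(a: np.ndarray, name: str, hint: str = "") -> np.ndarray:
    """Invert a symmetric positive-definite matrix via Cholesky.

    Raises NumericalRankError naming `name` if the factorization fails.
    """
    try:
        c, low = scipy.linalg.cho_factor(a, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as err:
        msg = f"matrix {name} is numerically singular / not positive definite"
        if hint:
            msg += f"; {hint}"
        raise NumericalRankError(msg) from err
    inv = scipy.linalg.cho_solve((c, low), np.eye(a.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)  # symmetrize away factorization round-off


def solve_mem(g: GenotypeMatrix, y: PhenotypeVector, vc: VarianceComponents,
              center: bool = False) -> MixedModelSolution:
    """Solve the marker-effect model mixed model equations.

    Returns mu_hat, p marker effects, and the explicit (p+1) x (p+1)
    inverse of the coefficient matrix (needed downstream for leverages).
    """
    y.check_aligned(g)
    Xs = build_design_mem(g, center=center)
    p = g.n_markers
    A = Xs.T @ Xs
    A[np.arange(1, p + 1), np.arange(1, p + 1)] += vc.lambda_ratio
    Ainv = spd_inverse(A, "X*'X* + D*lambda")
    sol = Ainv @ (Xs.T @ y.values)
    return MixedModelSolution(
        mu_hat=float(sol[0]), effects=sol[1:], model_kind="MEM", coefficient_inverse=Ainv
    )


def genomic_covariance(g: GenotypeMatrix, vc: VarianceComponents,
                       add_residual: bool = False) -> np.ndarray:
    """The n x n genomic covariance ``XX' sigma2_beta`` (= var(u)).

    With ``add_residual=True`` returns ``V = XX' sigma2_beta + I sigma2_e``,
    the phenotypic covariance, which is positive definite for sigma2_e > 0.
    Symmetric exactly by construction.
    """
    K = g.dosages @ g.dosages.T
    K = 0.5 * (K + K.T)
    V = K * vc.sigma2_beta
    if add_residual:
        V[np.diag_indices_from(V)] += vc.sigma2_e
    return V


def solve_bvm(g: GenotypeMatrix, y: PhenotypeVector, vc: VarianceComponents,
              jitter: bool = False) -> MixedModelSolution:
    """Solve the breeding-value model mixed model equations.

    Requires XX' nonsingular (typical when n < p). With ``jitter=True`` a
    ridge of 1e-8 * trace(XX')/n is added to the diagonal of XX' before
    inversion, for use on rank-deficient genotype sets; off by default so
    rank problems surface as errors.
    """
    y.check_aligned(g)
    n = g.n_individuals
    K = g.dosages @ g.dosages.T
    K = 0.5 * (K + K.T)
    if jitter:
        K[np.diag_indices_from(K)] += 1e-8 * np.trace(K) / n
    Kinv = spd_inverse(K, "XX'",
                       hint="use the marker-effect model (order p+1) or enable jitter")
    # coefficient matrix of [mu, u]: [[n, 1'], [1, I + Kinv*lambda]]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = n
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = Kinv * vc.lambda_ratio
    A[np.arange(1, n + 1), np.arange(1, n + 1)] += 1.0
    Ainv = spd_inverse(A, "Z*'Z* + G*lambda")
    rhs = np.concatenate([[y.values.sum()], y.values])
    sol = Ainv @ rhs
    return MixedModelSolution(
        mu_hat=float(sol[0]), effects=sol[1:], model_kind="BVM", coefficient_inverse=Ainv
    )


def fitted_values(g: GenotypeMatrix, sol: MixedModelSolution) -> np.ndarray:
    """Per-individual fitted values mu_hat + genetic value, either model."""
    if sol.model_kind == "MEM":
        return sol.mu_hat + g.dosages @ sol.effects
    return sol.mu_hat + sol.effects
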