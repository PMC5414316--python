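"""Core data containers: genotypes, phenotypes, variance components,
mixed-model solutions.

Conventions
-----------
* Genotypes are allele dosages coded 0/1/2 (count of the reference allele
  at a biallelic marker). No missing values are permitted; missingness is
  a load-time error, never imputed.
* Phenotypes are assumed pre-corrected for every fixed effect except the
  overall mean, so the only fixed effect in any model here is the
  intercept.
* ``lambda_ratio`` is the ridge / shrinkage parameter of the mixed model
  equations, lambda = sigma2_e / sigma2_beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import DataError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "VarianceComponents",
    "MixedModelSolution",
]


def _as_labels(labels: Sequence, n: int, what: str) -> list[str]:
    out = [str(x) for x in labels]
    if len(out) != n:
        raise DataError(f"expected {n} {what} labels, got {len(out)}")
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise DataError(f"duplicate {what} ids: {dupes}")
    return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """An n x p allele-dosage matrix with row/column identifiers.

    Parameters
    ----------
    dosages
        n x p array; every entry must be exactly 0, 1 or 2.
    individual_ids
        n row labels (coerced to str, must be unique).
    marker_ids
        p column labels (coerced to str, must be unique).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise DataError(f"dosages must be 2-D, got shape {d.shape}")
        n, p = d.shape
        if n < 2 or p < 1:
            raise DataError(f"need n >= 2 individuals and p >= 1 markers, got {n} x {p}")
        if not np.all(np.isfinite(d)):
            raise DataError("missing/non-finite genotype entries are not allowed")
        if not np.isin(d, (0.0, 1.0, 2.0)).all():
            bad = d[~np.isin(d, (0.0, 1.0, 2.0))]
            raise DataError(f"genotype dosages must be 0, 1 or 2; found e.g. {bad.flat[0]!r}")
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "individual_ids", _as_labels(self.individual_ids, n, "individual"))
        object.__setattr__(self, "marker_ids", _as_labels(self.marker_ids, p, "marker"))

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @classmethod
    def from_array(cls, dosages, individual_ids=None, marker_ids=None) -> "GenotypeMatrix":
        """Build from a bare array, generating ``ind{i}`` / ``m{j}`` labels."""
        d = np.asarray(dosages, dtype=float)
        if individual_ids is None:
            individual_ids = [f"ind{i + 1}" for i in range(d.shape[0])]
        if marker_ids is None:
            marker_ids = [f"m{j + 1}" for j in range(d.shape[1])]
        return cls(d, list(individual_ids), list(marker_ids))


@dataclass(frozen=True)
class PhenotypeVector:
    """n phenotype values, pre-corrected for nuisance fixed effects,
    aligned with a :class:`GenotypeMatrix` by individual id."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise DataError("phenotypes must all be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "individual_ids", _as_labels(self.individual_ids, v.size, "individual"))

    def __len__(self) -> int:
        return self.values.size

    def check_aligned(self, g: GenotypeMatrix) -> None:
        if self.individual_ids != g.individual_ids:
            raise DataError(
                "phenotype individual ids do not match genotype ids "
                f"(first mismatch: {_first_mismatch(self.individual_ids, g.individual_ids)})"
            )


def _first_mismatch(a: list[str], b: list[str]) -> str:
    if len(a) != len(b):
        return f"length {len(a)} vs {len(b)}"
    for x, y in zip(a, b):
        if x != y:
            return f"{x!r} vs {y!r}"
    return "none"


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the additive genomic model.

    sigma2_beta : per-marker effect variance.
    sigma2_e    : residual variance.
    sigma2_L    : large variance assigned to the overall mean when it is
                  treated as a random effect (strategy II); must dominate
                  sigma2_e (enforced: sigma2_L >= 100 * sigma2_e).

    ``lambda_ratio = sigma2_e / sigma2_beta`` is derived.
    """

    sigma2_beta: float
    sigma2_e: float = 1.0
    sigma2_L: float = 1000.0

    def __post_init__(self):
        if not (self.sigma2_beta > 0 and np.isfinite(self.sigma2_beta)):
            raise DataError(f"sigma2_beta must be finite and > 0, got {self.sigma2_beta}")
        if not (self.sigma2_e > 0 and np.isfinite(self.sigma2_e)):
            raise DataError(f"sigma2_e must be finite and > 0, got {self.sigma2_e}")
        if not (self.sigma2_L >= 100.0 * self.sigma2_e):
            raise DataError(
                f"sigma2_L={self.sigma2_L} too small: the random-mean device requires "
                f"sigma2_L >= 100 * sigma2_e = {100.0 * self.sigma2_e}"
            )

    @property
    def lambda_ratio(self) -> float:
        return self.sigma2_e / self.sigma2_beta

    @classmethod
    def from_lambda(cls, lambda_ratio: float, sigma2_e: float = 1.0,
                    sigma2_L: float | None = None) -> "VarianceComponents":
        """Construct from the shrinkage ratio lambda = sigma2_e/sigma2_beta.

        sigma2_e defaults to 1 so that sigma2_beta = 1/lambda.
        """
        if not (lambda_ratio > 0 and np.isfinite(lambda_ratio)):
            raise DataError(f"lambda must be finite and > 0, got {lambda_ratio}")
        if sigma2_L is None:
            sigma2_L = max(1000.0, 100.0 * sigma2_e)
        return cls(sigma2_beta=sigma2_e / lambda_ratio, sigma2_e=sigma2_e, sigma2_L=sigma2_L)


@dataclass(frozen=True)
class MixedModelSolution:
    """Solution of the mixed model equations.

    ``effects`` holds p marker effects for the marker-effect model (MEM)
    or n breeding values for the breeding-value model (BVM). The inverse
    of the coefficient matrix is retained because leave-one-out leverages
    are quadratic forms in it; memory is O((k+1)^2) with k = p (MEM) or
    n (BVM).
    """

    mu_hat: float
    effects: np.ndarray
    model_kind: Literal["MEM", "BVM"]
    coefficient_inverse: np.ndarray = field(repr=False)

    def __post_init__(self):
        e = np.asarray(self.effects, dtype=float).ravel()
        object.__setattr__(self, "effects", e)
        ci = np.asarray(self.coefficient_inverse, dtype=float)
        if ci.shape != (e.size + 1, e.size + 1):
            raise DataError(
                f"coefficient_inverse shape {ci.shape} inconsistent with {e.size} effects"
            )
        if not np.allclose(ci, ci.T, rtol=0, atol=1e-8 * max(1.0, np.abs(ci).max())):
            raise DataError("coefficient_inverse is not symmetric within solver tolerance")
        object.__setattr__(self, "coefficient_inverse", ci)

    @property
    def solution_vector(self) -> np.ndarray:
        """(mu_hat, effects) stacked, matching the MME ordering."""
        return np.concatenate([[self.mu_hat], self.effects])
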