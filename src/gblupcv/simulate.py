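"""Synthetic genotype/phenotype data: random-mating population with an
additive polygenic trait.

The generator mimics the structure typical of genomic-prediction
benchmarks: a founder pool at Hardy-Weinberg equilibrium, a fixed number
of discrete (non-overlapping) generations of random mating at constant
population size, then a final expanded offspring generation that is
returned. Loci are unlinked biallelic markers; there is no mutation,
selection or pedigree tracking. Phenotypes are y = X beta + e with iid
normal marker effects scaled so the realized narrow-sense heritability
matches the target h2, and the true effects are returned for recovery
tests. The simulated overall mean is 0; callers can add a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .types import GenotypeMatrix, PhenotypeVector

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the random-mating simulation.

    n_founders       : breeding population size, held constant across
                       generations (default 100).
    n_generations    : discrete non-overlapping generations of random
                       mating after the founders (default 10).
    n_offspring      : size of the final, returned generation (default 1000).
    n_markers        : number of unlinked biallelic loci.
    founder_maf_range: founder allele frequencies are drawn uniformly in
                       this interval; (0.1, 0.5) avoids near-monomorphic
                       columns.
    h2               : target narrow-sense heritability of the simulated
                       trait, in (0, 1).
    seed             : RNG seed; all output is reproducible from it.
    """

    n_founders: int = 100
    n_generations: int = 10
    n_offspring: int = 1000
    n_markers: int = 100
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise DataError(f"n_founders must be >= 2, got {self.n_founders}")
        if self.n_generations < 1 or self.n_offspring < 1 or self.n_markers < 1:
            raise DataError("n_generations, n_offspring and n_markers must all be >= 1")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise DataError(f"founder_maf_range must satisfy 0 < low <= high < 1, got {self.founder_maf_range}")
        if not (0.0 < self.h2 < 1.0):
            raise DataError(f"h2 must be in (0, 1), got {self.h2}")


def _mate(parents: np.ndarray, n_children: int, rng: np.random.Generator) -> np.ndarray:
    """One generation of random mating with unlinked loci.

    Each child draws two distinct parents uniformly; at every locus each
    parent transmits one allele, Bernoulli(dosage/2), independently.
    """
    n_par = parents.shape[0]
    pa = rng.integers(0, n_par, size=n_children)
    # resample to force the second parent distinct from the first
    ma = rng.integers(0, n_par, size=n_children)
    clash = ma == pa
    while clash.any():
        ma[clash] = rng.integers(0, n_par, size=int(clash.sum()))
        clash = ma == pa
    p_pa = parents[pa] / 2.0
    p_ma = parents[ma] / 2.0
    child = (rng.random(p_pa.shape) < p_pa).astype(np.int8) + (
        rng.random(p_ma.shape) < p_ma
    ).astype(np.int8)
    return child


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate dosages for the final generation of a random-mating population.

    Founders are drawn as Hardy-Weinberg Binomial(2, f_m) genotypes at
    per-locus frequencies f_m ~ Uniform(founder_maf_range). Each of the
    following n_generations is produced by random mating at constant size
    n_founders, except the last, which is expanded to n_offspring rows and
    returned. Warns (does not fail) if every locus drifts to monomorphism.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(*cfg.founder_maf_range, size=cfg.n_markers)
    pop = rng.binomial(2, freqs, size=(cfg.n_founders, cfg.n_markers)).astype(np.int8)
    for gen in range(cfg.n_generations):
        last = gen == cfg.n_generations - 1
        pop = _mate(pop, cfg.n_offspring if last else cfg.n_founders, rng)
    if np.all(pop.std(axis=0) == 0):
        warnings.warn("all simulated loci are monomorphic; increase sizes or MAF range")
    ids = [f"g{cfg.n_generations}_ind{i + 1}" for i in range(cfg.n_offspring)]
    markers = [f"snp{j + 1}" for j in range(cfg.n_markers)]
    return GenotypeMatrix(pop.astype(float), ids, markers)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig,
                        seed: int | None = None) -> tuple[PhenotypeVector, np.ndarray]:
    """Additive phenotypes y = X beta + e at target heritability cfg.h2.

    Marker effects are iid normal, rescaled so the sample variance of the
    genetic values X beta is exactly h2 while var(e) = 1 - h2; the
    realized heritability then fluctuates around h2 only through the
    residual draw. Returns the phenotypes and the true (rescaled) effects.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    beta = rng.standard_normal(g.n_markers)
    gv = g.dosages @ beta
    v = gv.var()
    if v == 0:
        raise DataError(
            "genetic values have zero variance (all markers monomorphic?); "
            "simulate more polymorphic markers"
        )
    scale = np.sqrt(cfg.h2 / v)
    beta = beta * scale
    gv = gv * scale
    e = rng.standard_normal(g.n_individuals) * np.sqrt(1.0 - cfg.h2)
    y = gv - gv.mean() + e  # overall mean 0
    return PhenotypeVector(y, g.individual_ids), beta


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeVector, np.ndarray]:
    """Convenience: genotypes + phenotypes + true effects in one call."""
    g = simulate_genotypes(cfg)
    y, beta = simulate_phenotypes(g, cfg)
    return g, y, beta
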