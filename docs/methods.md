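# Methods

## Model

Both model forms describe the same additive genetic architecture. The
marker-effect model (MEM) is

    y = 1μ + Xβ + e,    β_k ~ iid N(0, σ²β),    e_i ~ iid N(0, σ²e),

with `X` the n×p allele-dosage matrix (0/1/2) and `y` assumed
pre-corrected for every fixed effect except the overall mean μ. BLUP of
(μ, β) solves `(X*'X* + Dλ)β̂* = X*'y` with `X* = [1 X]`,
`D = diag(0, 1, …, 1)` and λ = σ²e/σ²β. The breeding-value model (BVM)
reparameterizes to `u = Xβ` with var(u) = XX'σ²β and solves a system of
order n+1 instead of p+1. Predictions of any linear function of the data
are identical between the two; the package picks the cheaper system
(`strategy="auto"`: MEM when n ≥ p, BVM otherwise) and the test suite
uses the equivalence as a cross-model oracle.

Assumptions inherited from this setup: a single general mean (no other
fixed effects), homoscedastic iid residuals, known variance components
(no REML step), complete genotypes (missingness is rejected at load, not
imputed), and raw 0/1/2 coding by default — an optional column-centering
flag exists for users but changes only μ̂'s interpretation, not the
leave-one-out residuals.

## Leave-one-out identities

Ridge-BLUP is a linear smoother, so the prediction of record j from the
other n−1 records is available without refitting:

    ê_j = (y_j − x*_j'β̂*) / (1 − H_jj),   H = X*(X*'X* + Dλ)⁻¹X*',

and identically with C = Z*(Z*'Z* + Gλ)⁻¹Z*' for the BVM (strategy I).
The implementation reuses the full-data β̂* and the explicit coefficient
inverse; the rank-one downdate that proves the identity is never formed.
Leverages satisfy 0 < H_jj < 1 strictly when λ > 0; a leverage within
1e-12 of 1 raises a hard error (the observation would predict itself)
rather than propagating NaN.

Strategy II treats μ as a random effect with a large variance σ²L, so
var(y) = V* = X*ΣX*' + Iσ²e with Σ = diag(σ²L, σ²β I), and borders V*
with y'y and y' into the (n+1)-order matrix Q. For each j, the 2×2 block
of Q⁻¹ at rows/columns (0, 1+j) — index selection, never a permutation
matrix — yields

    ê_j  = −q^(1+j,1) / det,     PEV_j = q^(1,1) / det,
    det  = q^(1,1) q^(1+j,1+j) − q^(1,(1+j)) q^((1+j),1),

and reliability_j = 1 − PEV_j / V*_jj. By the partitioned-inverse
identity PEV_j equals the conditional variance
V*_jj − V*_{j,−j}V*_{−j,−j}⁻¹V*_{−j,j}: it depends on genotypes and
variance components only, never on phenotypes, which the tests assert
at 1e-8.

The naive oracle refits literally: for MEM, the reduced normal equations
on X*_{−j}; for BVM, a fit on the n−1 training individuals followed by
the standard GBLUP prediction of an unphenotyped individual,
μ̂ + k_j'K_train⁻¹û_train with k_j the genomic covariances to the
training set. Both equal the closed forms exactly in exact arithmetic;
the suite checks 1e-6 relative agreement across hundreds of random
instances.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| σ²β | trait² per marker | — (or via λ) | marker-effect variance; shrinkage strength |
| σ²e | trait² | 1 | residual variance; with only λ given, σ²e = 1 is assumed |
| λ = σ²e/σ²β | — | — | the ridge parameter of the mixed model equations |
| σ²L | trait² | max(1000, 100·σ²e) | diffuse variance of the random mean (strategy II); enforced ≥ 100·σ²e |

σ²L trades approximation error against conditioning: the strategy-II
residuals approach strategy I as σ²L grows (tested non-increasing over
1e3 → 1e5 → 1e7; ~1e-3 relative agreement at 1e3, ~1e-6 at 1e7), while
very large values degrade Q's condition number. The default 1000 keeps
both effects mild for trait variances of order 1.

## Numerical choices

- All SPD systems (both MME coefficient matrices, training-set XX'
  blocks) are solved by Cholesky; failure raises an explicit
  numerical-rank error naming the matrix, never a silent pseudo-inverse.
  BVM requires XX' nonsingular (typical when n < p); for rank-deficient
  cases an opt-in jitter of 1e-8·trace/n is available, and the error
  message points to the MEM route.
- Q is symmetric but in general *indefinite* — the y'y border does not
  necessarily dominate — so Q⁻¹ comes from a Bunch–Kaufman symmetric
  solve, not Cholesky.
- The coefficient inverse is formed explicitly (order p+1 or n+1,
  memory O((max(n,p)+1)²)) because leverage extraction needs its
  diagonal quadratic forms.
- Degenerate strategy-II denominators (|det| < 1e-12·q^(1,1)) raise an
  error naming the individual.
- Predictions are defined as ŷ_j := y_j − ê_j, so that identity is
  bit-exact by construction.
- PRESS is an exact sum of squared residuals over the requested mask
  and is additive over any partition; accuracy is the Pearson
  correlation of (y, ŷ) over the mask and is refused (not NaN-ed) for
  masks of size < 2 or constant vectors — the CLI report maps this to
  an `NA` with a warning.

## Synthetic data

`simulate_genotypes` emulates a closed random-mating population:
founders at Hardy-Weinberg proportions with per-locus allele
frequencies uniform on (0.1, 0.5) (chosen to avoid near-monomorphic
columns), then discrete non-overlapping generations at constant size
(default 100) with two distinct parents per offspring and independent
transmission per locus, and a final generation expanded to the requested
size (default 1000). `simulate_phenotypes` draws iid normal marker
effects rescaled so the sample variance of Xβ is exactly the target h²
against a residual variance 1 − h², and returns the true effects for
recovery tests. Defaults (100 founders, 10 generations, 1000 offspring)
match the population structure typical of genomic-prediction benchmarks.

What the simulator deliberately omits: linkage and recombination maps
(the LOOCV algebra is agnostic to LD), mutation, selection, pedigree
bookkeeping, genotyping error and missingness. Passing tests on this
data therefore demonstrate the correctness of the LOOCV algebra and the
scaling behaviour of the routes — not robustness to LD structure,
ascertainment or data-quality artefacts of real marker panels.

## Problem sizes used in the checks

The oracle-equivalence sweep uses 200 random instances with n ∈ [3, 12],
p ∈ [1, 20] and λ ∈ {0.1, 1, 10, 100}. The realistic-scale checks use
1000×100 (MEM route; naive refit over all 1000 records) and 1000×10000
(BVM route; naive refit spot-checked on 20 individuals, since 1000
order-1000 refits add nothing beyond the spot-check). Wall-clock
comparisons between naive and efficient routes are reported
qualitatively (efficient < naive on 1000×100); absolute timings are
hardware-dependent and never asserted.

## Known limitations

- Single trait, single general mean; no additional fixed effects,
  no REML, no pedigree (A-matrix) relationships.
- Reliability uses V*_jj, which contains σ²L, so reported reliabilities
  are compressed toward 1; their ordering and spread across individuals
  are informative, their absolute level is dominated by the diffuse
  mean. (PEV itself is unaffected.)
- k-fold CV for k < n and leave-cluster-out are out of scope; the
  closed forms here are specific to leaving out a single record.
- BVM strategies require XX' of full rank n; duplicated genotype rows
  (clones, identical twins) break this and are reported as such.
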