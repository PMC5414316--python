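# gblupcv

Exact leave-one-out cross-validation (LOOCV) for genomic BLUP, at the
cost of a single model fit.

## The problem

Genomic prediction regresses phenotypes on genome-wide marker dosages and
uses the fitted model to predict the genetic merit of new candidates.
Before trusting those predictions, breeders and quantitative geneticists
quantify predictive ability by cross-validation; with small training
sets, leave-one-out is the natural choice because every training fold is
as large as possible. Done naively it means refitting the model *n*
times. Because ridge-BLUP is a linear smoother, that is unnecessary: all
*n* leave-one-out residuals follow in closed form from one fit.

`gblupcv` implements the closed forms for both standard formulations of
the model and validates them against a literal refitting oracle.

## The model and the shortcuts

**Marker-effect model (MEM).** With `y` (length *n*) pre-corrected for
all fixed effects except the overall mean, `X` the n×p dosage matrix
(0/1/2 coding), and iid marker effects with variance σ²β:

```
y = 1μ + Xβ + e,      λ = σ²e / σ²β
(X*'X* + Dλ) β̂* = X*'y,   X* = [1 X],  D = diag(0, 1, …, 1)
```

The leave-one-out residual for record *j* needs no refit:

```
ê_j = (y_j − x*_j'β̂*) / (1 − H_jj),   H = X*(X*'X* + Dλ)⁻¹X*'
```

One solve of order p+1 — the route of choice when n ≥ p.

**Breeding-value model (BVM / GBLUP).** The equivalent model fits
breeding values `u = Xβ` with covariance `XX'σ²β`; its mixed model
equations have order n+1, cheaper when p ≥ n. The same identity holds
with the diagonal of `C = Z*(Z*'Z* + Gλ)⁻¹Z*'` (strategy I). A second
BVM route (strategy II) treats the mean as a random effect with a large
variance σ²L, borders the phenotypic covariance `V* = X*ΣX*' + Iσ²e`
with `y'y` and `y'` into a matrix `Q`, and reads every residual — plus
each individual's prediction error variance (PEV) and reliability
`1 − PEV/var(y_j)` — from entries of `Q⁻¹`.

Aggregates: `PRESS = Σ ê_j²` and accuracy = Pearson correlation of
`y_j` with `ŷ_j = y_j − ê_j`, over all individuals or any subgroup mask
(e.g. terminal offspring only).

## Worked example

A 3-individual, 5-marker dataset with λ = 10 is built in
(`gblupcv.toy_dataset()`); `python examples/worked_example.py` prints:

```
leverages (diagonal of the hat-type matrix; how strongly each
observation predicts itself — identical for both model forms):
  MEM H_jj: [0.46 0.51 0.55]
  BVM C_jj: [0.46 0.51 0.55]

leave-one-out residuals e_hat_j (phenotype minus the prediction
from a model trained on the other individuals):
  MEM (hat identity)     [ 1.129  1.205 -2.656]  PRESS=9.781
  BVM strategy I         [ 1.129  1.205 -2.656]  PRESS=9.781
  BVM strategy II        [ 1.129  1.206 -2.654]  PRESS=9.772
  naive refitting        [ 1.129  1.205 -2.656]  PRESS=9.781
```

The four routes agree: strategy II differs in the third decimal because
its diffuse random mean (σ²L = 1000) only approximates a fixed mean.
The large negative residual for individual 3 says its phenotype is much
lower than the other two individuals' data would predict.

The same run from the shell:

```bash
gblupcv loocv --genotypes toy.csv --phenotypes toy.pheno.tsv \
        --strategy mem --lambda 10 --out report.tsv
```

Other entry points: `gblupcv simulate` writes a random-mating
population (founder pool, discrete generations, additive trait at a
target h²) to CSV/TSV; `gblupcv loocv --strategy auto` picks MEM when
n ≥ p and BVM otherwise, reads CSV/TSV or PLINK RAW dosages, and writes
a per-individual TSV report plus a key=value summary;
`gblupcv benchmark` times naive vs efficient routes (wall-clock,
machine-dependent, never asserted). The `examples/` scripts cover the
same capabilities from Python.

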