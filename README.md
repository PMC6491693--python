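# latentscale

Scaling the variance of latent variables in confirmatory factor analysis
(CFA) without changing the model.

## The problem

In CFA the covariance matrix of `p` manifest variables is reconstructed as

```
Sigma = Lambda Phi Lambda' + Theta
```

with loadings `Lambda` (p × q), latent variances/covariances `Phi` (q × q)
and diagonal error variances `Theta`.  The variance parameter `phi` of a
latent variable carries real information — for instance, how much a trait
factor contributes to responding compared with a method factor in a
multitrait–multimethod (MTMM) design — but its value depends on an arbitrary
identification choice: fix one loading to 1 (marker variable), fix `phi`
itself to 1 (reference group), or constrain the sum (effect coding) or sum
of squares of the loadings to a criterion number `p_c`.  Different choices
give different `phi` estimates, which makes the raw parameter hard to
interpret.

`latentscale` makes these choices interchangeable.  All of them are scalar
multiplications: for any constant `c > 0`,

```
(c Lambda) (Phi / c²) (c Lambda)'  =  Lambda Phi Lambda'
```

so the *true part* of the implied covariance — and therefore model fit — is
invariant, while the scaled variance parameter transforms as
`phi_sc = phi / c²`.  Each scaling method is just a particular `c`:
`c = 1/lambda_i` (marker), `c = sqrt(phi/phi_sc)` (reference group),
`c = p_c / Σ lambda_i` (effect coding), `c = sqrt(p_c / lambda'lambda)`
(squared-loadings criterion).  Setting `p_c = 1` in the squared-loadings
method transfers a factor's whole explained variance `lambda'lambda · phi`
into `phi_sc`, which makes factors of the same model directly comparable and,
for a unidimensional model, equals the nonzero eigenvalue of
`lambda phi lambda'`.

The package is aimed at psychometricians and methodologists working with
structural equation models who want variance parameters they can compare —
across factors, identification conventions, or criterion numbers.

## What's inside

- `latentscale.model` — factor-model containers (`CFAModel` etc.), the
  implied covariance `Lambda Phi Lambda' + Theta`, and `constancy_distance`,
  the max entrywise change of the true part between two solutions.
- `latentscale.scaling` — per-method scaling constants, `rescale` (which
  provably preserves the true part; latent covariances are divided by
  `c_j·c_k`), and `criterion_sensitivity_table` for equal-loading design
  grids.
- `latentscale.comparison` — criterion-1 contributions per factor
  (`comparison_scaling`), explained variance, eigenvalue cross-check.
- `latentscale.estimation` — a minimal ML CFA fitter (`fit`) that imposes
  any of the three identifications at estimation time (effect coding by
  exact reparameterisation), plus fit indices (χ², RMSEA, SRMR, CFI, GFI),
  standard errors, and a diagonal-adjustment helper for correlation input.
- `latentscale.simulate` — synthetic populations (including two-source
  trait/method designs), Gaussian score sampling, Monte-Carlo recovery
  studies.
- `latentscale.io` / `latentscale.cli` — delimited-matrix I/O, run
  manifests, and a thin `latentscale` command with subcommands `scale`,
  `table`, `compare`, `fit`, `simulate`.

## Worked example

Fit one population covariance under all three identifications and compare
(`examples/04_fit_identifications.py`):

```
marker           F = 0.00e+00  phi-hat = [0.49 0.25]  comparison-scaled = [1.47 0.75]
reference_group  F = 0.00e+00  phi-hat = [1. 1.]      comparison-scaled = [1.47 0.75]
effect_coding    F = 1.78e-15  phi-hat = [0.49 0.25]  comparison-scaled = [1.47 0.75]
constancy distance marker vs reference_group: 3.78e-09
constancy distance marker vs effect_coding: 1.63e-08
```

The raw variance parameters `phi-hat` differ with the identification, but
every fit reproduces the same true part (distance ≈ 0) and the same
criterion-1 contributions: factor 1 explains 3·0.7² = 1.47 units of
indicator variance, factor 2 explains 3·0.5² = 0.75.  The other scripts in
`examples/` cover rescaling a given solution, the criterion-number
sensitivity grids, trait-vs-method comparison, a synthetic MTMM workflow and
a Monte-Carlo recovery study; each prints a short interpretation of its
numbers.

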