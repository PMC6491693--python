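# Methods

## Model and constancy

The covariance structure is the standard CFA model
`Sigma = Lambda Phi Lambda' + Theta` with diagonal `Theta`.  Everything in
the package revolves around one algebraic fact: for any positive scalar `c`
applied to a factor's loading column together with `1/c²` applied to its
variance parameter, the true part `Lambda Phi Lambda'` is unchanged.  With
several factors we apply an independent constant per factor, i.e. a positive
diagonal matrix `D = diag(c_1 … c_q)`: `Lambda* = Lambda D` and
`Phi* = D⁻¹ Phi D⁻¹`, so latent covariances are divided by `c_j·c_k`.  Since
`(Lambda D)(D⁻¹ Phi D⁻¹)(D Lambda') = Lambda Phi Lambda'` for *any*
symmetric `Phi`, the package allows correlated factors throughout; only
`true_part_entry`, the scalar per-entry sum
`σ_τij = Σ_k λ_ik φ_kk λ_jk`, is restricted to diagonal `Phi` (with
covariances present the cross terms are missing from that sum, so the call
is refused and `implied_covariance` must be used).

`constancy_distance` quantifies preservation as the maximum absolute
entrywise difference between two true parts.  It deliberately operates on
`Lambda Phi Lambda'` only: if the true part is constant with respect to a
given sample matrix, the error part `Theta` is implied constant as well, so
including `Theta` would add nothing and would hide scaling errors behind
large error variances.

## Scaling methods

Four methods, each a choice of `c` per factor:

| method | constraint | constant | default |
|---|---|---|---|
| marker | `c·λ_i = 1` | `1/λ_i` | — (index required) |
| reference group | `phi/c² = target` | `sqrt(phi/target)` | target = 1 |
| effect coding | `Σ c·λ = p_c` | `p_c / Σλ` | — (`p_c` required) |
| squared loadings | `Σ (c·λ)² = p_c` | `sqrt(p_c / λ'λ)` | — (`p_c` required) |

`c` must be strictly positive, so the marker loading must be positive
(negative markers would flip the factor's direction) and the loading sum
must be positive for effect coding.  The scaled variance is always
`phi_sc = phi/c²`; a negative `phi` (estimation can produce one) propagates
its sign into `phi_sc` and is flagged, never clamped.  Criterion numbers are
accepted as arbitrary positive reals — a proportion like "1/2" of an odd `p`
simply yields a non-integer `p_c`.

Two consequences drive the sensitivity grids: `phi_sc = phi·p·λ²/p_c` for an
equal-loading design, so (a) a larger criterion number gives a smaller
scaled variance, and (b) tying `p_c` to `p` by a fixed proportion removes
the dependence on the number of indicators, while an absolute `p_c` makes
`phi_sc` grow with `p`.

Comparison scaling sets `p_c = 1` for every factor, making each
`phi_sc = λ'λ·phi` — the factor's explained variance, and the nonzero
eigenvalue of `λ phi λ'` in the one-factor case.  For correlated factors the
per-factor contributions use the diagonal of `Phi` only; the cross-factor
share of the true-part trace is reported separately as `shared_variance`,
because attributing it to either factor would be arbitrary.  Ranking ties
are broken by input factor order (stable sort).

## ML estimation

The fitter minimises `F = log|Sigma| + tr(S Sigma⁻¹) − log|S| − p` over the
free parameters with BFGS and analytic gradients
(`dF/dθ = tr[(Sigma⁻¹ − Sigma⁻¹ S Sigma⁻¹)·dSigma/dθ]`), stopping at
gradient norm 1e-7 (max 2000 iterations).  Starting values are scale-aware:
free loadings `0.5·sqrt(s_ii)`, latent variances 1, latent covariances 0,
error variances `0.5·s_ii`.  A non-PD `Sigma` during the line search returns
a large penalty pointing back toward the interior rather than an exception.
Identification constraints live in the parameterisation itself — marker
loadings and reference variances are fixed values, and effect coding
reparameterises one loading per factor as `p_c − Σ(others)` — so every
constraint holds to machine precision at every iterate, and fitting the same
population matrix under different identifications converges to rescalings of
one identical solution (observed true-part agreement ~1e-8 on population
input).

Degrees of freedom are `p(p+1)/2 − (number of free parameters)`; a dependent
effect-coding loading is not counted as free.  Fit indices use the standard
definitions: `χ² = (n−1)F`, `RMSEA = sqrt(max(χ²−df,0)/(df(n−1)))` (0 with a
note when `df = 0`), SRMR as the root mean square of the standardized
residuals over the lower triangle including the diagonal, CFI against the
independence baseline (which has the closed form
`F_b = Σ log s_ii − log|S|`, `df_b = p(p−1)/2`), and
`GFI = 1 − tr[(Sigma⁻¹(S−Sigma))²]/tr[(Sigma⁻¹S)²]`.  A correlation matrix
is accepted and treated as a covariance matrix, with a logged caveat that
χ²-based indices assume covariance input; the `adjust_diagonal` helper
substitutes a new main diagonal (recording the change) to repair negative
error variances without touching the systematic, off-diagonal entries.

Standard errors (optional, off by default) come from
`(2/(n−1)) H⁻¹` with `H` the central-difference Hessian of the analytic
gradient (step `1e-5·max(1,|θ|)`).  The ratio estimate/SE is invariant to
the scale choice, which the suite checks across criterion numbers 1 and 3.
Negative Hessian diagonal entries (non-PD Hessian at a boundary or saddle)
yield `NaN` standard errors rather than imaginary ones.  Heywood cases are
returned as estimated with a note; the optimiser places no bounds on error
variances.

## Synthetic data

The generator emulates the measurement equation `x = mu + Lambda xi + delta`
with Gaussian `xi ~ N(0, Phi)` and `delta ~ N(0, Theta)` — Gaussian because
that is the assumption under which the ML discrepancy is the likelihood; the
generator does not produce non-normal, ordinal or missing data, so passing
tests say nothing about robustness to those features of real data.  Sample
covariances use the `n−1` denominator.  Defaults mirror the equal-loading
study designs used throughout (loadings in {0.2, 0.4, 0.6} on 4–12
indicators, unit latent variances); when error variances are not given they
are set to `1 − communality` (floored at 0.1), i.e. roughly unit-variance
indicators.  Raw scores are generated (rather than sampling a Wishart
matrix directly) so the same stream can feed future raw-data estimators;
each replicate of a recovery study draws its seed from a single
`numpy.random.Generator` spawned from the study seed, making every study
reproducible from one integer.

Problem sizes in the test suite follow the desk-scale designs: random models
at `p ≤ 12`, `q ≤ 3`; 500 random rescaling plans; 20 population matrices for
the identification-equivalence suite; 50 replicates at `n = 5000` for the
Monte-Carlo recovery of the criterion-scaled variance (population value
0.16, tolerance 0.02 chosen as several times the Monte-Carlo standard error
of the mean at that design).

## Numerical choices and limitations

- Symmetry and constancy tolerances default to 1e-10 absolute; all algebra
  is dense double precision at `p ≤ ~50`, where round-off is orders of
  magnitude below that.  Products `Lambda Phi Lambda'` are symmetrised
  (`(M+M')/2`) so stored matrices equal their transposes exactly.
- Degenerate inputs: all-zero loading columns make every criterion-based
  constant undefined; `comparison_scaling` flags such factors and reports a
  zero contribution instead of dropping them, while the constant functions
  raise.
- Exact reproduction of published MTMM variance estimates from the classic
  3-trait × 3-method correlation matrix is out of scope: that matrix is
  external to the package and the sample size behind its χ² is not
  available.  The packaged reliability vector and adjusted diagonal support
  the workflow; the demo runs on a synthetic population clearly labelled as
  such.  Both routes to criterion-scaled variances are available: post-hoc
  rescaling of a reference-group solution and constrained re-estimation
  (effect coding at fit time); on population input they agree.
- No standard-error recalculation under post-hoc rescaling, no mean
  structures, no multi-group or categorical-indicator models.
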