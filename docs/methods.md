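# Methods

This note records the statistical model, the estimation machinery, the
numerical choices, and the known limitations of `ordmi`.

## Model

Observed ordinal responses are generated from a probit item factor model.
Person *i*'s latent response to item *j* in group *k* is

    Y*_ij = nu_j + lambda_j eta_i + eps_ij,
    eta_i ~ N(alpha_k, psi_k),   eps_ij ~ N(0, theta_jk),

and the observed category is determined by item thresholds:
`Y_ij = c` iff `tau_j^(c) <= Y*_ij < tau_j^(c+1)`, with
`tau^(0) = -inf` and `tau^(C) = +inf`. Intercepts `nu_j` are fixed at 0
(absorbed by the thresholds). Marginally,

    P(Y_j = c) = Phi((tau^(c+1) - lambda_j alpha_k)/s_jk)
               - Phi((tau^(c)   - lambda_j alpha_k)/s_jk),
    s_jk = sqrt(lambda_j^2 psi_k + theta_jk),

which the `moments` module uses for closed-form category probabilities,
expected item/scale scores, distribution skewness, and the analytic bias
of observed mean differences.

### Invariance levels

- **configural**: same pattern, all measurement parameters group-specific;
- **metric**: loadings equated (for dichotomous items this adds nothing
  that is empirically identified, so the sequence skips it);
- **scalar**: thresholds equated as well;
- **strict**: unique variances equated too.

Only under *full strict* invariance do observed (sum/mean) score
comparisons compare groups fairly; factor-mean comparisons are valid
from (partial) scalar invariance for polytomous items but require strict
invariance for dichotomous items, because with binary indicators the
threshold/uniqueness trade-off leaves the scalar model empirically
underidentified (see Limitations).

## Built-in generating parameter sets

`load_parameter_set(name, C)` returns ten-item sets for `C` in {2, 5, 7}:

- `negatively_skewed` / `positively_skewed`: all loadings 0.6, unique
  variances 0.64 (total latent-response variance 1), thresholds chosen so
  every item's marginal distribution has skewness about -1 (or +1).
- `BACS`: loadings and thresholds patterned after an empirical
  brief-assessment scale with heterogeneous loadings (1.31-2.68) and
  unit unique variances. Its tabulated thresholds are on the
  *standardized* latent-response scale; the loader stores those as
  `thresholds_std` and converts to the raw scale
  (`tau_raw = tau_std * sqrt(lambda^2 psi + theta)`) for generation.

`make_condition(set, n_k, C, p_ni, d_ni, alpha_f)` builds a two-group
population: groups share loadings and thresholds; the focal group's
unique variances on the *last* `p_ni` items are multiplied by `d_ni`;
the focal factor mean is `alpha_f` (reference fixed at 0, both factor
variances 1). These defaults deliberately mirror a realistic survey
setting — skewed item distributions, modest loadings, noninvariance
confined to unique variances — and are also exactly the study conditions
the Monte Carlo harness exercises.

Simulation draws `eta` and `eps` from independent, seeded Generators per
group and discretizes; no approximation is involved.
`replication_seed(base, key, r)` derives independent 31-bit streams per
condition and replication, so grids are reproducible and
embarrassingly parallel with identical results at any worker count.

## Stage-one estimation

Univariate thresholds are `Phi^{-1}` of cumulative proportions; an
observed empty category raises `EmptyCategoryError` (treated downstream
as a nonconverged replication for model-based analyses). Polychoric
correlations are two-stage ML: with thresholds fixed at stage one, the
bivariate log-likelihood is maximized over `rho` by bounded scalar
optimization on (-0.999, 0.999).

The asymptotic covariance `Gamma` of the stacked statistics (thresholds,
then the upper triangle of the correlations) is estimated by influence
functions. Threshold influence is `(1{y<=c} - F_c)/phi(tau_c)`; the
correlation influence corrects the score for threshold estimation using
closed-form bivariate-normal cross-information (`dPhi2/drho = phi2`,
`dPhi2/dh = phi(h) Phi((k - rho h)/sqrt(1-rho^2))`). This avoids
numerical differentiation entirely and is validated against a
nonparametric bootstrap in the test suite.

Bivariate-normal rectangle probabilities use a NumPy port of Genz's BVND
algorithm (Gauss-Legendre 6/12/20-node rules on the arcsine-transformed
integral, with the asymptotic expansion for |rho| >= 0.925), validated
to ~2e-16 against `scipy.stats.multivariate_normal`.

## Model fitting

The multigroup model is fitted by diagonally weighted least squares:
minimize `(s - sigma(x))' W^{-1} (s - sigma(x))` with
`W = diag(Gamma/n)` stacked over groups, using a trust-region
least-squares optimizer with an analytic Jacobian of the implied
standardized thresholds and correlations (theta parameterization
throughout). Two identification styles are provided:

- `lavaan` style (harness default): unique variances fixed at 1 in both
  groups while thresholds/loadings are group-specific (configural,
  metric); once thresholds are equated (scalar+), the focal unique
  variances, factor mean and variance become free.
- `liu` marker style (pipeline default): one marker item's loading and
  one threshold per item (plus the marker's second threshold) are
  equated from the configural model on; reference unique variances fixed
  at 1, focal free; reference factor mean 0 and variance 1. This keeps
  the factor scale linked at every stage so stages differ only by the
  constraints under test. For dichotomous items the configural model
  additionally fixes the focal factor variance at 1 (it is otherwise
  unidentified with only one threshold per item).

Robust inference uses the mean-and-variance-adjusted (scaled-and-shifted)
statistic: with `U = W^{-1} - W^{-1} Delta (Delta' W^{-1} Delta)^{-1}
Delta' W^{-1}` and `S` the full sampling covariance of the statistics,
`T* = a T + b`, `a = sqrt(df / tr((US)^2))`, `b = df - a tr(US)`.
Nested models are compared with the corresponding scaled difference
test, and score-based modification indices
`MI = g^2 / (delta' W^{-1} P S P' W^{-1} delta)` rank equality
constraints for the partial-invariance search. Standard errors are
sandwich estimates; the factor-mean Wald test is
`z = alpha_f_hat / se`. RMSEA (with a noncentral-chi-square confidence
interval), CFI against an independence baseline, and SRMR are available
via `fit_measures`.

### Convergence and admissibility

A fit counts as converged only if the optimizer reports success, the
relative gradient is below 1e-6, all free unique/factor variances and
implied latent-response variances are positive (otherwise the fit is
flagged as a Heywood case), and the information matrix has reciprocal
condition number >= 1e-8. Heywood and numerically singular fits count as
nonconverged in the Monte Carlo summaries; rejection rates are computed
among converged replications, with the convergence rate reported
alongside.

## Invariance-testing pipeline

`run_sequence` selects the marker as the highest-loading item from a
pooled single-group fit, then walks configural -> (metric) -> scalar ->
strict, testing each stage against the last retained model with the
scaled difference test. A rejected stage triggers a partial search:
constraints are freed one at a time in descending modification-index
order until the freed model is no longer distinguishable from the last
retained model. At the strict stage, items whose thresholds or loadings
were already freed get their uniqueness constraint freed as well (a
parameter equated on a non-invariant item would be meaningless). The
report records per-item invariance levels and an explicit verdict on
whether observed-mean and factor-mean comparisons are defensible.

## Monte Carlo harness

`run_condition`/`run_grid` simulate replications of a condition and
summarize three analyses: the pooled-variance t-test on person-level
scale scores, and factor-mean Wald tests in the scalar model and in the
correctly specified (partial) strict model. Raw bias for the t-test is
measured against the *invariant-focal-group* analytic benchmark, so it
isolates the distortion caused by noninvariance rather than by
categorization.

Default replication counts in the examples, tests, and
`scripts/acceptance.py` (300-1,000 per condition) are this package's own
choice to keep runtimes in minutes on one CPU; tolerances scale
accordingly as binomial Monte Carlo margins. Nothing else about the
conditions is scaled or tuned.

## Limitations

- Two groups only; one factor; no missing data.
- The dichotomous scalar model is *empirically* underidentified: it
  counts as identified by parameter/moment arithmetic, but the data
  carry almost no information separating focal unique variances from
  factor mean/variance once only one threshold per item is available.
  Expect low convergence rates and a wildly inflated factor-mean Wald
  test in that model — reproducing this pathology is a feature, and the
  pipeline therefore requires full strict invariance before trusting
  any mean comparison with binary items.
- Analytic bias results are exact for the model, but the printed
  positively-skewed thresholds are mirror images of the negative set
  only to their printed precision, so the bias mirror-symmetry holds to
  about 3 decimals, not machine precision.
- The two-stage polychoric estimator assumes underlying bivariate
  normality; `Gamma` is asymptotic and noticeably noisy below roughly
  n = 200.
- Extremely skewed binary items (e.g. the `BACS` set dichotomized at its
  0.2% category) routinely produce empty cells at realistic sample
  sizes; such replications are counted as nonconverged rather than
  patched with continuity corrections.
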