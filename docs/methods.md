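# Methods

## The biometric model

`twinpath.cholesky` fits multivariate Cholesky variance-component models to
wide-format same-sex twin-pair data by full-information maximum likelihood.
Each component (additive genetic A, shared environment C — optional, and
individual-specific environment E) is parameterized by a lower-triangular
path matrix with as many latent factors as phenotypes, which guarantees a
positive-semidefinite component covariance and makes the factor shares
directly readable: factor k contributes `path[j,k]² / Var_j` of phenotype
j's variance.  Latent A factors correlate 1 within MZ pairs and 0.5 within
DZ pairs, C factors correlate 1 in both groups, E factors never cross
twins.  Dominance (D) components are out of scope: they are indicated only
when MZ correlations exceed twice the DZ correlations, a configuration the
supported designs do not target.

Missing co-twins are handled by FIML: each pair contributes the
multivariate-normal density of its observed sub-vector, so single
responders enter through the p-dimensional marginal.  Internally pairs are
grouped by (zygosity, sex, missingness pattern) and the objective is
evaluated from per-group sufficient statistics (n, mean, scatter), which
makes the cost of one likelihood evaluation independent of sample size.

### Sex limitation in same-sex designs

Only "common effects" style sex limitation is identifiable without
opposite-sex pairs.  Four variants are implemented:

- `none` — all structural parameters shared across sex;
- `scalar` — one free positive scalar per phenotype multiplies the female
  total SD (equivalently each variance component by its square), so
  standardized components are sex-equal by construction;
- `common_effects` — separate per-phenotype female scalings for A and E
  (and C), i.e. sex-specific component magnitudes with shared correlation
  structure;
- `free` — fully separate per-sex path matrices.

The six-model comparison ladder pairs ACE and AE with, in order,
sex-specific paths (`free`), `scalar`, and `none`.  The `free` variant is
used for the "sex-specific parameters" rungs because its parameter
bookkeeping (10 C paths per sex for four phenotypes, hence a df gap of 20
between the ACE and AE rungs) matches the published ladder's df column; the
constrained `common_effects` variant remains available and is the stricter
reading of "correlation matrices equal across sexes".  Means are estimated
freely per phenotype and per sex, equal across twins and zygosity groups.

### Optimization and numerics

The objective and its analytic gradient (chain rule through the path
products, the female scalings and the missing-data restriction) are
minimized by L-BFGS-B over raw paths with log-parameterized diagonals, so
reported diagonals are positive and the Cholesky sign indeterminacy never
arises.  Convergence is declared at gradient max-norm 1e-6 (optimizer
default tolerances otherwise).  The default start is moment-based: A is
initialized from the MZ/DZ cross-twin covariances (`2(C_MZ − C_DZ)` for
ACE, a weighted MZ/DZ average for AE), E from the residual within-twin
covariance, each eigenvalue-clipped to the PSD cone with a small diagonal
floor; scalars start at 1 and means at the observed per-sex means.  This
start converges reliably in our testing, so the default is a single run;
`FitConfig(n_starts=...)` adds randomly perturbed restarts and keeps the
best optimum, and non-convergence is flagged on the returned fit rather
than raised.  Since E has a strictly positive diagonal under the
log-parameterization, the expected pair covariance is positive definite
throughout optimization; the direct `minus2_loglik_fiml` entry point, which
accepts arbitrary (possibly singular) specifications, returns +inf for a
non-PD restricted covariance.

Degrees of freedom count the non-missing phenotype values entering the
likelihood minus the free parameters, and the default AIC is the Mx-style
`-2LL - 2·df` (the conventional `-2LL + 2·k` is available via
`FitConfig(aic_convention="conventional")`).  Ladder selection takes the
lowest AIC, ties broken by fewer parameters.

### Confidence intervals

Bootstrap intervals resample pairs with replacement within zygosity-by-sex
strata, refit warm-started at the original optimum (200 resamples by
default) and report percentile bounds.  Profile-likelihood intervals invert
the LR test: an SLSQP equality-constrained refit pins the target
(a standardized share or an rg/re entry) while a bracketing search plus
bisection finds the parameter value at which -2LL rises by the chi-square
quantile.  Estimates within 0.02 of a boundary (0/1 for shares, ±1 for
correlations) are flagged as effectively one-sided.  Bootstrap coverage is
exercised in the test suite on a bivariate AE design (800 pairs, true
rg = 0.6) over 150 simulated cohorts with 200 resamples per interval —
sized for a single-CPU run while keeping the coverage standard error near
1.8% — and must land in [0.90, 0.99] at nominal 95%.

## The synthetic cohort generator

`build_generating_model` constructs AE truths from variance shares and
correlation matrices: `A = D_a^{1/2} Rg D_a^{1/2}`,
`E = D_e^{1/2} Re D_e^{1/2}`, factored to lower-triangular paths (a pivoted
Cholesky that tolerates singular components, so zero-heritability
phenotypes yield exactly zero genetic paths).  Shares that do not sum to
one — the published anxiety-depression (0.40 + 0.49) and MS pain
(0.49 + 0.50) values are rounded — are renormalized proportionally, since
the model requires unit standardized totals.

The reference cohort emulates the study conditions of a middle-aged
Norwegian same-sex twin sample: 373 MZ + 385 DZ pairs (746/770
individuals), 64.6% female pairs, ages irrelevant to the model and not
simulated, and a 16% single-responder rate applied MCAR at the pair level
(one co-twin's whole block removed; no mechanism beyond MCAR is modelled).
Phenotypes are standardized latents — raw questionnaire scales are not
reproduced — with per-sex means at zero and female SD scalars of 1.1 per
phenotype, a single choice representing the reported "somewhat larger"
female variance (no numeric value is published).  Twin-1/twin-2 assignment
is exchangeable by construction of the symmetric pair distribution.

Ordinal item batteries are produced by thresholding
`λ·latent + √(1−λ²)·noise` at standard-normal cutpoints: the six fatigue
items use cutpoints at the quantiles of the published category marginals
with loadings 0.60–0.85 (population first eigenvalue ≈ 3.8, Cronbach's
alpha ≈ 0.88 on the continuous scale); the 3-item MS pain and 5-item
anxiety-depression batteries use marginals chosen to match the published
scale means and alphas.  Because the recorded responses are ordinal,
observed product-moment correlations are attenuated relative to their
continuous-latent values — observed alpha ≈ 0.83 and first eigenvalue
≈ 3.3–3.5 for the fatigue items; a polychoric treatment would remove the
attenuation and is deliberately out of scope.  Consequently passing tests
demonstrate the structural claims (unidimensionality, retention-rule
agreement, threshold-implied marginals) rather than exact equality with
statistics computed on the real items.  Covariates (5-level education,
three binary health indices with prevalences 0.409 / 0.086 / 0.113) are
drawn independently per twin and can carry linear effects into named
phenotypes; they are independent of the genetic structure, which real
covariates need not be.

The generator does not emulate: opposite-sex pairs, dominance, non-normal
continuous phenotypes, informative missingness, age effects, or
measurement-error structure beyond the item thresholds.

## Psychometrics and phenotypic association

Scale descriptives report per-category percentages and percent symptomatic
(score ≥ 2 by default).  Cronbach's alpha uses the variance formula with
listwise (default) or pairwise-complete handling.  Factor extraction is
maximum likelihood on the product-moment correlation matrix (items treated
as continuous, as in the replicated analysis), via statsmodels' Factor;
Heywood cases are floored at uniqueness 0.005 and flagged.  Factor
retention offers the eigenvalue > 1 rule, the raw eigenvalue curve for
scree inspection (no automatic elbow — the judgment is subjective), and
Horn's parallel analysis with 1000 standard-normal replicates at the 95th
percentile by default (common practice; the source analysis does not state
its settings).  Because twin pairs are not independent, item-level analyses
accept a twin-1/twin-2 subsample selector.

GEE regression uses a Gaussian family with identity link, the twin pair as
cluster, an exchangeable working correlation by default (independence
available; with it the point estimates equal OLS exactly) and sandwich
standard errors (model-based SEs via `robust=False`).  Pearson correlations
carry Fisher-z intervals.  Hierarchical variance blocks report least-squares
R² per block in a twin subsample.  The extreme-scorer filter removes
subjects whose item-mean on a scale reaches the threshold (default 3,
"considerable"), keeping half-pairs as single responders; on the reference
cohort it removes ≈5% of subjects, matching the published sensitivity
analysis, and is idempotent.  Missing data are handled by listwise deletion
within each association analysis.

## Problem sizes used in validation

Simulation-recovery checks use 20 seeded replicates of 800 pairs per design
(4-variate concurrent model, 4-variate longitudinal model, bivariate
neuroticism-stability model), averaging estimates across replicates;
sampling-distribution checks use 20,000+ pairs.  These sizes put
Monte-Carlo error comfortably inside the assertion tolerances (±0.03 for a
phenotypic correlation, ±0.05 for genetic correlations and variance
shares).

## Known limitations

- Ordinal phenotypes are generated but modelled as continuous; no
  liability-threshold biometric models.
- Only same-sex pairs; general (qualitative) sex limitation and
  opposite-sex DZ pairs are unsupported.
- Profile CIs rely on SLSQP equality-constrained refits and can be slow or
  tender near boundaries; bootstrap is the default.
- The published model-comparison table contains internally inconsistent
  cells (one Δ-2LL, two Δdf values, one AIC); the package reproduces the
  identity-consistent bookkeeping and makes no attempt to match the
  inconsistent cells.
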