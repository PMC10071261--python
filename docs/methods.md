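# Methods

This note records the statistical model, the conventions and numerical
choices baked into `mixglm`, and what the simulation-based validation does
and does not establish.

## Model

`MixtureGLM` fits a k-component finite mixture of exponential-family
regressions with canonical links. Three members are shipped:

| family   | link     | a(φ)  | dispersion |
|----------|----------|-------|------------|
| Gaussian | identity | σ²    | free, per component |
| Poisson  | log      | 1     | fixed |
| binomial | logit    | 1/m   | fixed |

Binomial responses are stored and computed on the **count scale**
y ∈ {0,…,m}; the count-scale log-likelihood kernel absorbs the
proportion-scale constant a(φ) = 1/m, which the family object still carries
explicitly (`Binomial.a_of_phi()`), so the count-based deviance formulas
need no extra factor. Offsets (log exposure) are accepted for the Poisson
family only; requesting one elsewhere is a configuration error rather than a
silent ignore, since an exposure offset has no standard meaning for the
other two members here.

### Estimation

EM on the complete-data log-likelihood: the E-step computes posteriors in
log space with per-row max subtraction; the M-step sets π_j to the mean
posterior and obtains (β_j, φ_j) from a posterior-weighted GLM fit. Because
the mixing-weight and regression blocks of the expected complete-data
log-likelihood have zero cross-derivatives they are maximised separately.

The weighted GLM fit is Fisher scoring / IRLS (identical for canonical
links): at most 100 iterations, convergence when the relative change in the
weighted deviance drops below 1e-10, with step-halving whenever a full step
would increase the weighted deviance. The Gaussian/identity case is solved
in one weighted least-squares step. A binomial linear predictor exceeding
|η| > 30 raises a separation warning. Rank-deficient weighted designs raise
rather than pseudo-solve.

EM control: convergence when the relative change of the observed-data
log-likelihood falls below 1e-8 (default), cap 500 iterations. **Every
iteration ends on an M-step**, so the stored coefficients are the exact
weighted-GLM optimum under the stored posteriors. This matters: the Gaussian
identity D_j = ED_j + RD_j relies on the orthogonality of weighted residuals
to the design, which holds exactly only at the M-step optimum of the very
weights used in the sums. (For Poisson and binomial the identity is
algebraic and holds at any evaluation point.)

Guards: a component whose soft size n̂_j falls below d + 2 aborts the fit
with a named degenerate-component error (the effective sample cannot
identify its d + 2 parameters); the Gaussian variance MLE is floored at
1e-10 to keep densities evaluable. An observation for which every
component's density underflows raises with the row index.

MAP classification breaks posterior ties deterministically toward the lowest
component index — reproducibility over randomisation.

Information criteria: BIC = −2ℓ + p·ln n with
p = (k−1) + k(d+1) + k·[φ free]. ICL is computed as BIC plus twice the
posterior classification entropy −Σ ẑ ln ẑ (0·ln 0 := 0). Entropy
conventions for ICL vary across software; this one makes ICL = BIC exact for
hard partitions, and the package does not treat ICL values as comparable
across implementations.

## Deviance measures

All measures are evaluated at the fixed soft partition ẑ and the fitted
dispersions φ̂_j, so they measure the contribution of the regressors and the
grouping, not of the dispersion. The local null mean is the posterior-
weighted response mean ȳ_j; the grand mean ȳ is the unweighted sample mean.

The generic kernels write b(·) at the canonical parameter of the mean
argument, i.e. b(θ(ȳ_j)); the family-dispatched closed forms (weighted sums
of squares for Gaussian; xlogy-based count forms for Poisson and binomial,
with 0·ln 0 := 0 at the saturated boundary) are the computation path, and
the test suite verifies each against twice the corresponding weighted
log-likelihood difference under the exact densities.

Two conventions deserve note:

- **Poisson with offset.** The default local null is the mean-based ȳ_j for
  every family, offset or not. An alternative offset-aware local null — a
  posterior-weighted intercept-only Poisson fit *including* the offset,
  giving a per-observation null mean — is available behind
  `deviance(offset_aware_null=True)`, default off. The mean-based
  definition keeps the measures comparable across families; the offset-aware
  variant answers "what does the covariate add beyond exposure?", and both
  satisfy the additive identities.
- **Gaussian total deviance** uses the fitted-model σ̂²_j in every bracket
  of cluster j's contribution, consistent with evaluating all compared
  models at the fitted dispersion.

`decompose()` asserts the additive identities (D_j = ED_j + RD_j within
1e-8 relative; TD — computed independently from the grand mean — equal to
BD + EWD + RWD) on every call and raises if they fail. Ratios with zero
denominators (TD = 0 for a constant response; D_j = 0) are NaN and listed in
`flags['undefined']`, never coerced to 0 or 1. For one-parameter families TD
is partition-free (Σ_j ẑ_ij = 1 collapses the double sum), which the tests
exercise by recomputing TD under different fits of the same data.

Adjusted variants use soft degrees of freedom (n̂_j − (d+1), n̂_j − 1
locally; n − k(d+1), n − k overall) and are flagged `descriptive_only`: the
soft partition, and with it the WD benchmark, changes whenever the model
changes, so comparisons of adjusted values across models are meaningless and
the package never includes them in its model-comparison (criteria) report.

Reported coefficient standard errors come from the posterior-weighted
observed Fisher information at convergence. They treat the partition as
fixed — the classical weighted-GLM approximation — and understate full
mixture uncertainty; they are reported for orientation, not inference.

## Initialization strategies

`initial_partition` provides: true simulated labels; MAP under the true
generating parameters; random short-EM (S restarts of H = 5 EM iterations
from i.i.d. uniform multinomial hard assignments, keeping the restart with
the highest log-likelihood); k-means (10 restarts, lowest within-cluster sum
of squares); PAM k-medoids (classic BUILD + SWAP on Euclidean
dissimilarities, implemented in-package); and a full-covariance Gaussian
mixture seeded by k-means. The clustering strategies operate on the raw,
unstandardised joint (X, y) rows. The GMM strategy uses k-means seeding
rather than hierarchical agglomeration; on well-separated data all
strategies agree (the package's initialization-agreement check), and near
degenerate overlap no seeding of a joint Gaussian mixture is authoritative.
Every strategy is deterministic given (data, seed); an empty cluster is
retried once with a fresh seed, then raises.

## Synthetic data and what the validation shows

`simulation.condition(family, id)` enumerates an 8-cell design per family —
class separation (small/large) × regression fit (poor/good) × sample size
(100/1000) — with fixed two-component coefficient grids, balanced weights
π₁ = 0.5, a single standard-normal covariate, and (binomial) m = 10 trials.
These parameter grids *are* the study conditions; they are not tuning knobs.
The Monte Carlo runner uses 250 replicates per condition by default,
replicate r seeded as base_seed + r, true-label initialization for the
reference tables, best-permutation component alignment before per-cluster
metrics (exhaustive for k ≤ 6, Hungarian beyond), and excludes-and-counts
failed replicates (> 5% flags the summary unreliable). The paired
initialization comparison reuses the same replicate data across strategies
so differences isolate the initialization effect.

What passing the Monte Carlo checks shows: under correctly specified,
moderately sized two-component DGPs, the EM plus decomposition pipeline
reproduces the published average ARI, NBD, local and overall R² to within
sampling error, recovers the generating parameters, and is insensitive to
initialization when clusters are well separated. What it does not show:
behaviour under misspecified families, overdispersion, covariate-dependent
mixing weights, d > 1 interactions, or the near-degenerate small-n/high-
overlap regime, where initialization demonstrably matters.

Problem sizes in the shipped validation — 250 replicates for the Monte Carlo
conditions, 100 random fits for the identity audit, 50 replicates for
parameter recovery, 100 for initialization agreement — were chosen so that
Monte Carlo standard errors sit well inside the comparison tolerances.

## Known limitations

- Canonical links only; no gamma / inverse-Gaussian members (the family
  interface extends, but they are not shipped or tested).
- No stochastic or classification EM estimation; hard 0/1 memberships can be
  supplied and frozen (`fit(init=labels, max_iter=0)`), which reproduces
  independent per-subset GLM fits.
- Mixture standard errors are the fixed-partition approximation.
- k-range scans report BIC/ICL for order selection; the deviance R² measures
  are deliberately excluded from that role.
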