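# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `saesmoke`.

## Design-based direct estimation

Prevalence of a binary smoking indicator in municipality *i* is estimated by
the Hájek ratio `p̂ᵢ = Σ wₖ yₖ / Σ wₖ` over the area's non-missing
respondents, with post-stratified weights by default (a flag selects raw
design weights). The plain inverse-probability sum `Σ yₖ/πₖ` estimates a
population *total*; normalizing by the estimated population size is what
turns it into a proportion, and the Hájek form is also invariant to
rescaling all weights — a property the tests assert.

The design variance treats households (clusters) as with-replacement
primary units and linearizes the ratio:

```
v(p̂) = n_c/(n_c−1) · Σ_c z_c² / W²,   z_c = Σ_{k∈c} w_k (y_k − p̂),  W = Σ w_k.
```

No finite-population correction is applied (sampling fractions within areas
are small). A single-cluster area falls back to respondent-level units; an
area observed as a census (all inclusion probabilities 1) has design
variance 0 and is flagged degenerate.

### Logit transform and its variance

The smoothing model needs `logit(p̂ᵢ)` and its variance. The delta method
gives `V̂ᵢ = v(p̂)/(p̂(1−p̂))²` and `logit_transform` implements exactly that.
Monte-Carlo calibration against the generator, however, shows the delta
form is strongly biased upward when an area contains only a handful of
cases (at true prevalence 0.04 with ~50 respondents it overstates the true
sampling variance of the logit by roughly a factor two, because `1/(p̂(1−p̂))²`
explodes for small random counts). A variance that is too large on average
gets absorbed into the observation term of the hierarchical model and
deflates the estimated between-area scale σ, which in turn narrows every
credible interval. `build_direct_table` therefore offers:

- `"delta"` — the textbook delta method;
- `"stabilized"` — the design-effect-scaled empirical-logit variance
  `deff·(1/(x+½) + 1/(n−x+½))` with `x = n·p̂` effective successes, which
  coincides with the delta method at moderate counts and is nearly unbiased
  at small ones;
- `"gvf"` — a generalized-variance-function form `deff/(n·p̄(1−p̄))`
  evaluated at the pooled national prevalence, so an area's likelihood
  weight is decoupled from its own sampling noise. This matters for rare
  outcomes: weighting by the area's own noisy count systematically favours
  areas that happened to observe more cases and biases the smoothed level
  upward;
- `"auto"` (the `DirectEstimator` default) — `"gvf"` when the median
  expected success or failure count per area is below 5, `"stabilized"`
  otherwise.

### Boundary estimates

Estimates of exactly 0 or 1 have no finite logit. Two policies exist:
`"exclude"` flags them degenerate so the model imputes the area spatially
(the `build_direct_table` default), and `"empirical-logit"` (the
`DirectEstimator`/pipeline default) replaces them by the continuity-
corrected `(x+½)/(n+1)` with the empirical-logit variance. Exclusion is
innocuous for common outcomes but zero-truncates the likelihood of rare
ones: for the ~2% heavy-smoking category at ~40–50 respondents per area,
nearly half the areas observe zero cases, and dropping them biased the
smoothed national level upward by more than a factor two in our
calibration runs. The continuity correction keeps those areas' information
("no cases in 42 respondents") in the likelihood.

## The BYM2 smoothing model

Observation model, for non-degenerate in-sample areas:
`logit(p̂ᵢ) ~ N(θᵢ, V̂ᵢ)` with `V̂ᵢ` known; `θᵢ = xᵢᵀβ + bᵢ`.

Random effect (BYM2 parameterization): `b = σ(√φ·u* + √(1−φ)·v)` with `u*`
the scaled ICAR field and `v` iid N(0,1). The ICAR precision is the graph
Laplacian scaled per connected component by the geometric mean of the
constrained pseudo-inverse diagonal, so `u*` has unit generalized marginal
variance and σ is interpretable as the total between-area scale regardless
of graph topology. Sum-to-zero is enforced per component; singleton
components have structured effect exactly 0 and rely on `v`.

Priors: `β ~ N(0, 1000·I)` on standardized covariates (zero mean, unit SD
across areas, so coefficients are per-SD log-odds effects); PC prior on σ,
i.e. exponential with rate `−log(α)/u` (`u=1, α=0.01` by default, sensitivity
setting `u=0.1`); uniform prior on φ.

### Sampler

Per iteration:

1. `(σ, φ)` — adaptive random-walk Metropolis on `(log σ, logit φ)` against
   the *marginal* posterior with β, u*, v all integrated out:
   `y ~ N(0, τ²XXᵀ + σ²φ·S + diag(V̂ + σ²(1−φ)))`, `S` the constrained
   scaled-ICAR covariance restricted to likelihood areas. The marginal
   update costs one `n_obs × n_obs` Cholesky per proposal and mixes freely
   of the latent field; a centered update (conditioning on the sampled
   field) was tried first and mixed badly (split-R̂ 1.2–1.4 for φ, σ stuck).
   The proposal scale adapts toward 30% acceptance during burn-in only.
2. `(β, u*)` — exact joint draw from the Gaussian full conditional (v
   marginalized into the noise), by dense Cholesky of the
   `(p + n_active) × (p + n_active)` precision, followed by conditioning by
   kriging on the per-component sum-to-zero constraints (a jitter of
   `1e-8·mean diag` regularizes the ICAR null space before the constraint
   removes it exactly).
3. `v` — exact conditional draw; off-sample areas from the prior.

Defaults: 4 chains × 5000 iterations, 2000 burn-in; convergence is flagged
(warning, never silent) when any split-chain R̂ of σ, φ or β exceeds 1.05.
Fixing `fix_sigma=0` turns the model into a Bayesian regression with known
noise, which the tests check against the closed-form conjugate posterior to
within MC error.

### Diagnostics

DIC uses the Gaussian logit-scale deviance: `DIC = D̄ + p_D`,
`p_D = D̄ − D(θ̄)`. CPO is estimated by the harmonic-mean identity
`CPOᵢ = [E(1/p(yᵢ|θᵢ))]⁻¹` computed in log space; areas whose normalized
importance-weight effective sample size falls below 10% of the draws are
flagged unstable. CPO estimates are verified against brute-force
leave-one-out refits on a 5-area instance in the test suite.

## Category decomposition

Separate fits of the nested ladder heavy ⊆ heavy+moderate ⊆ current ⊆ ever
are differenced per draw (moderate = (h+m) − h, light = current − (h+m),
former = ever − current, never = 1 − ever); negative differences are clamped
at zero and each 5-vector rescaled to sum to one. Draws are paired across
fits by index — the fits are independent models, and index-pairing is a
conservative coupling that preserves each fit's marginal uncertainty.
Clamping fires rarely when the ladder is well separated, and the rescale is
the identity whenever no clamp fired.

The stratified mortality scenario needs stratum-level compositions, while
the models are fitted at the area level. We disaggregate one area-level fit
by the weighted stratum-vs-national prevalence ratios estimated from the
survey (renormalized to the simplex per stratum), rather than fitting six
stratum-specific spatial models; this assumes the age–gender tilt of
smoking is shared across areas. In the generator that assumption holds by
construction, and an oracle run (true compositions through the same
machinery) shows the approximation contributes about 4% relative error to
area attributable deaths, versus ~30% from prevalence sampling noise.

## Attributable fraction and mortality

With exposure categories j (never = reference, RR 1):
`PAF = S/(1+S)`, `S = Σⱼ Pⱼ(RRⱼ−1)`. The denominator equals
`Σⱼ Pⱼ·RRⱼ` summed over *all* categories including never — the standard
multi-category Levin form, which stays below 1 for finite risks (a
denominator restricted to exposed categories would not).

Relative risks are gamma-distributed with moment matching:
`sd = (hi − lo)/(2·1.96)`, `shape = (RR/sd)²`, `rate = shape/RR`, so the
gamma mean reproduces the point estimate exactly; a zero-width CI is a
point mass. Categories sharing one published estimate (e.g. a single
"≥10 cigarettes/day" risk) share draws. The matching assumes a roughly
symmetric CI; for strongly asymmetric published intervals the gamma tails
deviate from the printed bounds by a few percent.

Scenario 1 standardizes both the stratum compositions and the stratum death
rates of each area to the national age–gender structure (direct
standardization over six strata) before a single PAF per area; scenario 2
computes PAF within each stratum with crude stratum deaths and sums. Both
use 1000 paired Monte-Carlo draws by default (doubling to 2000 moves totals
by well under 2%). Report tables round attributable deaths up to whole
deaths; percentages of total mortality use the unrounded mean against
standardized (scenario 1) or crude (scenario 2) totals.

## Synthetic-data generator

The generator emulates the essential features of a clustered national
health survey over ~100–600 municipalities:

- **Adjacency**: rook grid (most-square r×c, truncated) or a Delaunay
  triangulation of random points.
- **Populations**: lognormal sizes (mean 15,000 aged 15+, log-SD 0.6,
  floor 60), Dirichlet age shares around 34/44/22%, male share ~48%,
  Dirichlet education shares around 5/12/32/51%.
- **Truth**: `logit(current) = intercept + x_std β + b` with the BYM2
  convolution effect (defaults σ=0.5, φ=0.5); ever smoking sits a fixed
  logit shift above current (national 19% current, 42% ever); heavy /
  moderate / light split current smokers 2:10:7. Six age–gender strata tilt
  current and ever smoking by fixed factors (men more, 65+ less current but
  more former), renormalized within each area so the stratum-weighted
  current margin equals `expit(η)` exactly.
- **Survey**: areas sampled uniformly without replacement (default ~26% of
  areas), then equal-size households (4 persons) with cluster counts
  proportional to area size (target ≈ 50 respondents in an average area,
  giving the realistic 2–250 range; a flag fixes counts for benchmark
  designs), all household members interviewed. Inclusion probabilities are
  the product of the stage-wise selection probabilities; post-stratification
  factors per age–gender stratum make weighted margins match the simulated
  population exactly. A cluster-level logit random effect (ICC 0.05) makes
  household members alike; its Jensen shift of the marginal prevalence is
  removed by a second-order correction so the observable margin equals the
  recorded truth. Smoking status goes missing with education-dependent
  probabilities 23/23/21.7/16% (≈19% overall at national margins, with the
  low-vs-high education contrast of 23% vs 16%).
- **Mortality**: expected stratum deaths `N·rate_never·Σ Pⱼ RRⱼ` with
  never-smoker rates tuned to a crude overall rate near 1%/year; observed
  counts Poisson. The recorded truth is the stratum PAF on the true
  composition and `true SAM = observed deaths × true PAF`, so recovery
  benchmarks isolate estimation error from Poisson noise.

All randomness flows from one user seed through `numpy.random.SeedSequence`
spawning (one child per stage, fixed order), so identical seeds reproduce
byte-identical pipelines.

What the generator does **not** emulate: real municipality geography or
names, probability-proportional-to-size municipality selection, household
size variation, within-area covariate gradients (education does not affect
an individual's smoking within an area, making the missingness ignorable by
design), non-response beyond the smoking item, and any time dimension.
Passing tests therefore validate the estimation machinery under a
known-truth world of realistic difficulty; they do not certify accuracy on
a real survey, where covariate measurement, informative missingness, and
design details can bite harder.

## Benchmark sizes

The test-suite benchmarks use: 8 replicate fits for covariate-effect
recovery and for the DIC direction check; 10 survey-mimicking replicates
(pooled, ~1000 intervals) for 95%-interval calibration and shrinkage
containment; 3 end-to-end replicates for attributable-mortality recovery;
2 chains × 1200–1500 iterations per benchmark fit (package defaults remain
4 × 5000). These sizes give stable pass/fail behaviour for the properties
tested while keeping the full suite fast enough to run routinely.

## Known limitations

- The logit-normal observation model treats estimated design variances as
  known; with ~13 clusters per area they carry ~40% noise, which slightly
  attenuates covariate effects and can under-cover at extreme prevalences.
- Per-area attributable-death estimates inherit the prevalence sampling
  noise (~30% relative at 50 respondents per area when between-area
  variation is large); averages across areas are recovered much more
  accurately than individual areas.
- The harmonic-mean CPO estimator is noisy for influential observations;
  the effective-sample-size flag marks such areas rather than fixing them.
- Inference is MCMC, not a Laplace approximation; runtime grows with the
  cube of the number of areas per iteration (dense factorizations), which
  is comfortable to ~600 areas but not designed for thousands.
- No multiple imputation of missing smoking status (complete-case analysis
  per the pipeline's scope) and no individual-level covariate modelling.
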