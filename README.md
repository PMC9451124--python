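# saesmoke

Small-area estimation of smoking prevalence and smoking-attributable
all-cause mortality from complex health-interview-survey data.

National health surveys interview a few thousand people clustered in a
fraction of a country's municipalities, so municipality-level smoking
prevalence cannot be estimated directly: many areas have a handful of
respondents (design-based estimates swinging between 0 and 100%) and most
areas have none at all. `saesmoke` implements the standard small-area
workflow for this problem and carries it through to the mortality burden
attributable to smoking in every municipality — including the off-sample
ones — with full uncertainty propagation. Because real health-interview
microdata are access-restricted, the package ships a first-class synthetic
data generator that emulates the survey design (clustered sampling,
post-stratification weights, education-dependent item missingness, spatially
correlated true prevalence) with recorded ground truth, so every stage of
the pipeline can be validated end to end.

## The model

For municipality *i*, let `p̂ᵢ` be the Hájek (weight-normalized) design-based
prevalence of a binary smoking indicator with linearized design variance.
On the logit scale the smoothing model is

```
logit(p̂ᵢ) ~ N(θᵢ, V̂ᵢ)                 (design variance V̂ᵢ treated as known)
θᵢ = xᵢᵀβ + bᵢ
bᵢ = σ(√φ·u*ᵢ + √(1−φ)·vᵢ)             (BYM2 convolution random effect)
```

where `u*` is the scaled intrinsic-CAR (ICAR) field on the municipality
adjacency graph (unit generalized marginal variance, sum-to-zero per
connected component), `v` is iid standard normal, `σ ≥ 0` is the total
random-effect scale with a penalized-complexity prior
`P(σ > u) = α` (default `u = 1, α = 0.01`), and `φ ∈ [0,1]` is the spatial
mixing fraction (uniform prior). Inference is by MCMC: an adaptive
random-walk Metropolis step for `(σ, φ)` against the marginal likelihood
with the latent field integrated out, followed by an exact joint Gaussian
draw of `(β, u*)` and of `v`. Off-sample municipalities get posterior
prevalence through the covariates and the spatial conditional — they
"borrow strength" from sampled neighbours. Model fit is compared by DIC and
screened by per-area conditional predictive ordinates (CPO).

Four nested binary indicators (heavy ⊂ heavy+moderate ⊂ current ⊂ ever
smoking) are fitted separately and differenced draw-by-draw into the
5-category composition {heavy, moderate, light, former, never}; negative
differences are clamped to zero and each draw is rescaled to the simplex.

The population attributable fraction with multiple exposure categories is

```
PAF = Σⱼ Pⱼ(RRⱼ − 1) / (1 + Σⱼ Pⱼ(RRⱼ − 1)),
```

never smokers being the reference (RR = 1), and attributable deaths are
`SAM_i = D_i × PAF_i`. Relative risks from published meta-analyses (shipped
as a packaged table) are given gamma distributions moment-matched to their
95% CIs; 1000 Monte-Carlo draws pair a posterior composition draw with a
relative-risk draw. Two scenarios are reported: (1) composition and deaths
directly standardized to the national age–gender structure; (2) PAF and SAM
computed within six age–gender strata with crude stratum deaths and summed.

## Worked example

```bash
saesmoke run --config examples/demo.yaml --outdir demo_out
```

simulates a 100-municipality survey (~1,400 respondents in 26 sampled
municipalities), fits the four ladder models, and writes prevalence and
attributable-mortality tables. The log ends with lines like

```
INFO smoothed current: DIC=48.22 seed=1370054118 (1.4s)
INFO sam_scenario2 written (n_draws=1000, seed=149961662)
INFO pipeline done in 6.7s
```

and `demo_out/sam_scenario2.csv` begins

```
area,sam,sam_q2.5,sam_q97.5,pct_of_deaths,scenario
A0000,22,14,30,14.79,2
A0001,7,5,8,14.46,2
A0002,30,22,37,22.08,2
```

i.e. municipality A0000 had an estimated 22 smoking-attributable deaths
(95% interval 14–30), 14.8% of its total deaths. In this run the
design-based current-smoking estimates range from 4.2% to 54.1% across the
26 sampled municipalities while the smoothed posterior means span 12.6% to
41.0% over all 100 — the shrinkage that makes small-area estimates usable. The same objects are available as a library:

```python
import saesmoke as sae

graph = sae.generate_adjacency(100, "grid", seed=1)
pop, truth = sae.generate_population(graph, seed=2)
micro = sae.draw_survey(pop, truth, seed=3)
est = sae.DirectEstimator(outcome="current").fit(micro)
smoother = sae.BYMSmoother(covariates=("edu_low_share", "male_share"),
                           seed=4).fit(est.estimates_, graph=graph,
                                       covariates=pop.covariate_matrix(
                                           ["edu_low_share", "male_share"]))
smoother.summary_          # per-area mean and 95% interval
smoother.dic_, smoother.cpo_
```

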