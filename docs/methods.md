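# Methods

`mortprev` estimates the prevalence of opioid dependence from linked
drug-related mortality data: a cohort of known opioid-dependent people
(assembled from treatment and criminal-justice contacts) linked to the
national death register, together with the count of fatal drug-related
poisonings (fDRPs) *not* linked to the cohort and population denominators.
This note documents the model, its assumptions, the priors and numerical
choices, the synthetic-data generator used for validation, and the
limitations that validation revealed.

## Data structure

The unit of observation is a stratum: gender (male/female) × age band
(15–34 / 35–64) × region, crossed with financial year and opioid
substitution treatment status (on/off). For every stratum-year-treatment
cell the data give linked fDRP counts d and person-years at risk E; for
the estimation year each stratum additionally carries the unlinked fDRP
count d^miss, the observed cohort headcount n^obs, and the population
denominator P. Four years of mortality data are pooled because several
cells contain zero deaths in any single year.

## Model

**fDRP rates.** Linked deaths are Poisson,

    d_{g,t,s} ~ Poisson( pmatch · exp(η_{g,t,s}) · E_{g,t,s} ),
    η = β₀ + β_female + β_old + β_off + β_year
      + β_female×old + β_off×old + β_off×year + u_region,

with corner constraints (reference: male, younger band, on treatment,
first year) and u_region ~ N(0, σ²_region). Year is categorical, not
linear, so each year's level and its off-treatment offset are free.
`pmatch` is the probability that a death occurring inside the cohort was
correctly linked; it thins the observed linked counts, so exp(η) is the
*true*, linkage-corrected rate.

**Prevalence.** Group prevalence follows a logit-linear model,

    logit π_g = α_region + γ_old + γ_female + γ_old×female
              + v_region·female + w_region·old,

with unconstrained region intercepts and Normal random region
interactions (SDs σ_v, σ_w). The latent number of dependent people not
in the cohort is n^miss_g = π_g P_g − n^obs_g, kept continuous (it enters
only as a Poisson mean) and constrained non-negative by rejection
(log-likelihood −∞ for infeasible states).

**Unlinked deaths.** The identifying assumption is that people never
observed in the cohort are, by construction, not in treatment, and die at
the *off-treatment* rate of their stratum:

    d^miss_g ~ Poisson( λ_off,g · n^miss_g
                        + (1 − pmatch)(λ_on,g E_on,g + λ_off,g E_off,g) ),

where the second term is linkage leakage: the share of true cohort deaths
the linkage missed. Each unobserved person contributes one person-year in
the estimation year; the data provide no attrition information for them.

**Priors.** Regression coefficients and region intercepts: Normal(0, 10²)
(effectively flat at the scale of log rates and logit prevalences).
σ_region ~ Uniform(0, 5); σ_v, σ_w ~ Uniform(0, 2). `pmatch` carries the
single informative prior, Uniform(0.74, 0.84), reflecting external
evidence on linkage completeness; a model variant fixes pmatch = 1 to
expose the impact of that correction. All priors are configurable.

## Computation

The joint posterior is sampled by adaptive Metropolis-within-Gibbs over
parameter blocks: rate fixed effects; rate region scores; log σ_region;
pmatch; prevalence intercepts and coefficients; a common shift of all
region intercepts (the slowest posterior direction — the national
prevalence level); prevalence region scores; and the two prevalence log
SDs. Blocks that leave the linked-deaths likelihood unchanged re-evaluate
only the cheap unlinked-deaths term and are swept three times per
iteration. Proposal scales adapt by Robbins–Monro toward 23.4% (vector
blocks) or 44% (scalars) acceptance, and block proposal covariances are
re-estimated from the burn-in history every 200 iterations; all
adaptation stops at the end of burn-in, so retained draws come from a
fixed Markov kernel.

Random effects use the non-centred parameterisation u = σ·z with
z ~ N(0, 1) sampled directly; the centred form collapses into the
σ → 0 funnel under random-walk proposals. SDs are sampled as log σ with
the Jacobian term. Bounded-uniform SD priors become bound checks.

Chains are initialised at the crude total-rate estimate for β₀, zeros
elsewhere, and region intercepts at a factor 1.3–2.6 (drawn per chain, so
starts are overdispersed) of the largest observed cohort/population ratio
in the region — feasible by construction. Seeding uses
`numpy.random.SeedSequence(seed).spawn(chains)`: results are bit-for-bit
reproducible, and a single integer controls everything.

Defaults are 4 chains × 50,000 iterations with 10,000 burn-in and
thinning 5; the validation studies in the test suite use 2 chains × 6,000
(burn-in 3,000), which keeps a 50-replicate study under ten minutes on
one CPU while leaving split-chain R-hat for the national prevalence near
1.02. Convergence is flagged, not enforced: a result whose worst R-hat
exceeds the configured threshold carries `converged=False` and a warning.

Derived quantities — π_g, n^miss_g, group and national totals — are
computed per retained draw, so their credible intervals carry all
parameter uncertainty. Model comparison uses the DIC,
DIC = D̄ + p_D with p_D = D̄ − D(θ̄), computed from the retained draws and
the likelihood at the posterior mean.

With a single region level the region random effects (and the
region-interaction effects in the prevalence model) are dropped: they are
unidentifiable against the intercepts and only inject prior noise. This
affects the packaged region-collapsed table; multi-region data use the
full model.

**Crude multiplier.** The comparator model estimates N = D/λ with
λ | cohort ~ Gamma(a₀ + d_cohort, b₀ + E) (a₀ = b₀ = 0.001 by default)
and the benchmark mean μ_D | d ~ Gamma(d + 1, 1) under a flat prior. Both
posteriors are conjugate, so the summary is computed by direct Monte
Carlo rather than a Markov chain. Results are insensitive (< 1%) to
replacing the vague Gamma prior with its improper limit.

## Synthetic-data generator

`synthetic.default_scenario()` emulates the national case study: 36
strata (2 × 2 × 9 regions), 34.4M population aged 15–64, national
prevalence ≈ 0.80%, an in-cohort fraction of 0.6415, treatment coverage
0.769 of cohort person-time, pmatch 0.79, and four years of data with
person-time growing as the cohort accumulates (members contribute 0.839
person-years in a year, reflecting mid-year entry). Rate coefficients
were calibrated to the pooled four-year national summary table, and the
intercept and off-treatment coefficient then solved so that the expected
cohort size (≈176,000) and expected total fDRPs (≈454) match the case
study; the calibration is analytic (`TruthScenario.expected_counts`), not
fitted to any estimator output.

Counts are drawn hierarchically per group and year in a fixed order
(dependent count → cohort membership → person-time split → deaths by
treatment state → linkage thinning → unobserved deaths), from one seeded
stream, so datasets are byte-stable under a seed. The generator mirrors
the model's identification assumption — unobserved people contribute only
off-treatment time — and a multiplier on their mortality rate allows
probing violations of the equal-rates assumption.

What the generator does *not* emulate: individual treatment episodes and
the elevated risk in the weeks after leaving treatment, duration effects,
migration between strata, and secular changes in linkage quality. Passing
recovery tests on synthetic data therefore demonstrates internal
consistency of model and estimator, not robustness to these real-data
features.

## Validation results and known limitations

Fitting the package's own synthetic data shows two regimes:

* **Large counts** (populations scaled ×20): posterior medians of national
  prevalence are essentially unbiased (≈ +2%) and 95% CrIs cover the
  truth in line with their nominal level.
* **Case-study scale** (~450 deaths, 36 strata): posterior medians of
  national prevalence run ≈ 10–14% high and CrI coverage of the truth
  falls well below 95%. The mechanism is a many-nuisance-parameters
  effect: the 36 latent group counts n^miss_g are nearly free (the
  prevalence model has ~30 effective parameters) under near-flat
  logit-scale priors, and integrating them out tilts the marginal
  likelihood of the shared off-treatment rate level downwards by roughly
  f = n^obs/(n^obs + n^miss) per group. With ~36 groups against only
  ~60 estimation-year off-treatment deaths carrying direct rate
  information, the posterior shifts the estimation-year off rate down by
  ≈ 25–30%, inflating n^miss correspondingly. The effect is a property of
  the exact posterior (verified with long, well-mixed chains), not of the
  sampler, and it shrinks as death counts grow or strata are collapsed:
  the region-collapsed four-group national table is much less affected,
  which is why its estimates sit close to the crude expectations.

Users applying the model at similar scales should read national
prevalence estimates as potentially high by about a tenth and treat
region-stratified fits with sparse off-treatment deaths with particular
caution; sensitivity analyses that drop the year × treatment interaction
(removing the most weakly-identified rate parameter) give a useful lower
anchor.

Other limitations: no sub-regional estimation (sparse deaths), no
modelling of the linkage process itself beyond the scalar pmatch, and no
time-trend extrapolation — estimates refer to the single estimation year.
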