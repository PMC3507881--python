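# Methods

## The data and the question

The package analyses long-term monthly censuses of mushroom fruiting: on
(roughly) one day per month an observer walks a fixed route and records every
epigeous fruiting species. Each species belongs to a trophic guild —
ectomycorrhizal (ECM), litter-decomposing, wood-decomposing, or unclassified —
and the scientific questions are seasonal: which months differ in fruiting
richness, do the genera within a guild agree on the seasonal ordering, and
which climatic covariates drive the per-survey number of fruiting species in
each group. Hypogeous (below-ground fruiting) species are excluded because
their detection depends strongly on collector expertise.

## The presence/detection model

For survey *i* and species group *j*, let *N<sub>j</sub>* be the number of
distinct species of the group observed at least once over the whole census,
*X<sub>ij</sub>* the latent number actually fruiting, and *D<sub>ij</sub>*
the number detected:

* *X<sub>ij</sub>* ~ Binomial(*N<sub>j</sub>*, *p<sub>ij</sub>*)
* *D<sub>ij</sub>* ~ Binomial(*X<sub>ij</sub>*, *d*)
* logit *p<sub>ij</sub>* = α<sub>j</sub> + Σ<sub>k</sub> β<sub>jk</sub> x<sub>ik</sub>

Each species of a group fruits independently with the same probability
*p<sub>ij</sub>* and, if fruiting, is found with probability *d*. A zero
detection therefore mixes true absence with overlooked presence — the
zero-inflation that a plain binomial regression on *D* would mis-attribute to
over-dispersion. Marginally *D<sub>ij</sub>* ~ Binomial(*N<sub>j</sub>*,
*p<sub>ij</sub>d*), which is what the exact-likelihood oracle tests check.

Covariates *x<sub>ik</sub>* are z-standardized, so the β are standardized
partial regression coefficients: T (mean daily temperature over the trailing
30-day window ending on the survey date), MR (rainfall accumulated over the
same window), WR (rainfall over the trailing 7-day window) and Y (years
elapsed since the first survey, in 365.25-day years). Windows are closed at
both ends; a calendar-month window policy is available as a config switch.
"Trailing window" was chosen as the default because it is unambiguous for
surveys held mid-month. Standardization uses the sample sd (ddof = 1) over
the analyzed surveys, and the constants are stored so new surveys can be
projected onto the fitted scale.

### Priors and detection structures

α and β carry vague Normal(mean 0, variance 10<sup>6</sup>) priors; each
detection probability carries a flat Beta(1, 1) prior. Four detection
structures are supported:

* `per_survey_shared` (default): one *d<sub>i</sub>* per survey, shared
  across groups. Sharing across groups is what separates a bad survey day
  from a genuinely bad fruiting month and keeps the β identified relative to
  common detection.
* `per_survey_per_group`: one *d<sub>ij</sub>* per cell (weakly identified;
  provided for completeness).
* `constant`: a single *d* (mixes fastest; appropriate when detection effort
  is stable).
* `fixed_known`: *d* fixed, not sampled (used in calibration experiments).

With free per-survey detection, *p* and *d* are partially confounded; the
per-survey structures therefore mix more slowly and their intercepts should
be interpreted jointly with the detection level, not alone.

### Sampler

One sweep of the Metropolis-within-Gibbs sampler:

1. **Latent counts** — exact Gibbs draw from the full conditional
   *X* = *D* + Binomial(*N* − *D*, *q*) with
   *q* = *p*(1 − *d*) / (1 − *pd*): among undetected species, *q* is the
   probability of present-but-missed.
2. **Detection** — conjugate update: *d* | *X* ~ Beta(1 + ΣD, 1 + Σ(X − D)),
   sums over the cells sharing that *d*.
3. **Regression block** — per group, a joint random-walk Metropolis proposal
   on (α<sub>j</sub>, β<sub>j·</sub>) with a spherical Normal step. The step
   scale adapts every 50 iterations during burn-in toward a 0.3 acceptance
   rate (multiplicative Robbins-Monro-style update) and is frozen at the end
   of burn-in, preserving detailed balance for the retained draws. The
   binomial coefficient in the Binomial(*X*; *N*, *p*) likelihood does not
   depend on the block and cancels from the acceptance ratio.

Chains start overdispersed (regression block ~ Normal(0, 1), *X* = *D*,
*d* = 0.9), each chain seeded by a (seed, chain) seed sequence so runs are
bit-reproducible. Burn-in is discarded first, then every `thin`-th draw is
retained: `(n_iter − burn_in) // thin` draws per chain.

Full-scale defaults mirror the original analysis (3 chains × 400,000
iterations, 100,000 burn-in, thin 40). `ZIBConfig.desk()` — 3 chains × 5,000,
burn-in 1,000, thin 4 — is the problem size used throughout the tests,
simulation studies and the acceptance script; at the simulated census sizes
it converges (Rhat < 1.1) in seconds while keeping 1,000 draws per chain.

Convergence uses the Brooks-Gelman corrected potential scale reduction
factor per scalar parameter; constant identical chains return 1 by
convention. Exceeding the threshold (default 1.1) flags the output, it does
not raise. Credible intervals are equal-tailed percentile intervals (not
HPD); a coefficient is flagged at 95% / 99% when the interval excludes zero,
with the 99% interval containing the 95% one by construction.

## Seasonal statistics

**Monthly aggregation** assigns each survey's count to its calendar month;
nothing is averaged before testing, so within-month dispersion across years
is preserved.

**Steel-Dwass all-pairs comparisons.** For each month pair, the two samples
are jointly midranked; the rank sum is standardized by the tie-adjusted
variance, and √2·|t| is referred to the studentized range distribution with
k = number of compared months and infinite degrees of freedom (the standard
large-sample form, via `scipy.stats.studentized_range`). A max-|t|
permutation variant is provided as the small-sample oracle and agrees with
the asymptotic form on clear-cut cases. Months with fewer than two surveys
are excluded with a warning. An exactly tied pair has t = 0 and p = 1.

**Compact letters** come from the insert-and-absorb algorithm: two months
share at least one letter iff they do not differ significantly. Columns are
split on each significant pair, absorbed when contained in another, and
lettered in deterministic month order so repeated runs label figures
identically.

**Kendall's W.** Judges are genera, objects the calendar months, each genus
midranking the months by mean per-survey species count (the orientation is
configurable). W uses the tie-corrected denominator by default; the test is
χ² = m(n−1)W on n−1 df, with an optional permutation p from independent
within-row rank shuffles. Months without surveys are dropped from the
objects rather than imputed.

**Relative richness** is the z-score of the monthly mean counts over the
months with data (sample sd): the group's standardized seasonal profile.
If all monthly means are equal the profile is defined as all zeros, with a
warning; never-surveyed months are NaN.

## The synthetic census generator

The generator emulates the census's statistical structure, not its actual
record: daily temperature is a sinusoid peaking in mid-August (annual mean
15.96 °C, amplitude 12.1 °C, Normal noise sd 1.5 °C), giving January ≈ 4 °C
and August ≈ 28 °C; daily rainfall is Gamma (shape 0.35) with a seasonally
varying mean calibrated so the long-run annual total is ≈ 1480 mm, peaking
around the early-summer rainy season. Surveys are scheduled monthly on the
15th — 347 scheduled months of which ~274 survive the 21% independent
missingness, matching the realized census size. Guild pool sizes are the
observed guild richnesses (271 ECM / 137 litter / 236 wood).

Default effect sizes (logit scale, standardized covariates): the ECM-like
group α = −2.0, β = (0.8, 0.5, −0.1, 0.1) over (T, MR, WR, Y) — strongly
temperature- and rain-driven with a slight negative weekly-rain effect; the
litter-like group (−2.2; 0.3, 0.6, −0.05, 0) — moderately seasonal; the
wood-like group (−2.0; −0.2, 0.3, 0.1, 0.4) — weakly seasonal with a
time-dependent increase. Genus-level defaults jitter seven genera per guild
around these templates with per-coefficient sd 0.1 (ECM), 0.3 (litter) and
0.5 (wood), so ECM genera are highly concordant and wood genera
sign-heterogeneous — the qualitative pattern the concordance analysis is
meant to detect. Default true detection is a constant 0.8; a per-survey
Beta option exists.

Detected counts are materialized as the lowest-indexed species of each group:
the counts, not the identities, carry the model's information, and this keeps
the materialization deterministic (a shuffled-identity option exists for I/O
stress tests). All randomness descends from one root seed through named
substreams (climate, missingness, presence, detection, identity, genus
effects).

**What the generator does not emulate:** real species lists and genus
frequencies, multi-day weather autocorrelation (rain days are independent
draws), observer turnover or effort trends, within-group heterogeneity of
fruiting probability, and fruiting-body persistence across months. Passing
recovery tests therefore show the estimator is calibrated when the model's
independence assumptions hold — not that real censuses satisfy them.

## Numerical choices and degenerate inputs

* Overflow-safe inverse logit via `scipy.special.expit`; the
  presence-given-detection probability *pd* is clipped below 1 − 10⁻¹² before
  forming *q*.
* `p·d = 1` with *D* < *N* is rejected as impossible data.
* A covariate that is constant over the analyzed surveys standardizes to an
  all-zero column with a warning (its coefficient then has no likelihood
  contribution and returns its prior).
* Species never detected are excluded from *N<sub>j</sub>*.
* Compact-letter alphabets are single lowercase letters; more than 26 letter
  groups raises.

## Problem sizes used in the checks

The calibration experiment fits 20 simulated censuses (300 surveys, one
200-species group, detection fixed at its true 0.8) at desk scale and checks
95% interval coverage of each β (expecting ≥ 17/20) and Rhat < 1.1
throughout. The Steel-Dwass family-wise error is measured over 1,000 null
simulations of 3 months × 12 surveys. The Kendall-W implementation is checked
exhaustively against the defining formula on all untied 3×3 and 4×3 rank
matrices. These sizes make the whole suite run in about a minute while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* With per-survey free detection the intercepts and detection levels are
  only jointly identified; inferences about β are robust, absolute presence
  probabilities are not.
* The asymptotic Steel-Dwass reference is approximate for very small monthly
  samples; use the permutation method there.
* The printed p-value of the concordance test relies on the χ² approximation,
  which is rough for few judges; the permutation p is preferred for m < 7.
* No spatial or phylogenetic structure, no model comparison (DIC/WAIC), and
  no trend tests beyond the elapsed-years covariate.
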