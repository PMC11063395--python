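# Methods

## Cohort model and the rule engine

A patient record carries demographics, an exclusive therapy class (none,
VKA, DOAC, heparin, aspirin, P2Y12 inhibitor), the seven CCHR predictor
fields, the CT outcome and 30-day outcomes. Records are validated on
construction: adults only, INR recorded only under VKA therapy,
neurosurgery implies a positive CT. Combined anticoagulant +
anti-platelet therapy is deliberately not representable: the modelled
cohort's group counts are exclusive, and an exclusive enum keeps every
stratification a partition.

The rule engine evaluates the seven CCHR criteria — GCS < 15 at 2 h,
suspected open/depressed skull fracture, basal skull fracture sign,
vomiting ≥ 2, age ≥ 65 (high risk); amnesia before impact ≥ 30 min,
dangerous mechanism (medium risk) — and returns the verdict, the
triggered set and the risk tier. A missing predictor raises an
`IncompleteRecordError` naming the field; silently imputing "negative"
would bias met-rates in synthetic studies. "Dangerous mechanism" is an
input boolean, not derived from the mechanism category, because the
mapping between the two (is a fall > 3 m a "fall from elevation"?) is
under-determined; the generator keeps the two loosely consistent.

INR bands partition the positive reals: subtherapeutic ≤ 1.5 <
therapeutic < 2.5 ≤ overtherapeutic.

### The recorded-verdict field

One patient in the modelled cohort — a 74-year-old on aspirin whose GCS
was assessed on arrival rather than at the 2-hour mark — was recorded at
enrolment as *not* meeting the rule, although age ≥ 65 makes her met
under a literal application. Her haemorrhage is tabulated in the not-met
stratum. To reproduce that tabulation without corrupting the rule engine,
records carry an optional `cchr_met_recorded` field: stratification uses
the recorded verdict when present and the engine otherwise
(`stratify_by="recorded"`, the default), and `stratify_by="rule"` forces
pure rule evaluation as a sensitivity analysis. On the reference cohort
the toggle moves the headline comparison from 23/387 vs 1/122 to 24/388
vs 0/121. This is the one place where the recorded data and the rule
disagree, and the report flags it.

## Synthetic cohorts

`generate_cohort(spec)` draws a cohort from a `CohortSpec`: per-group
sizes and CCHR-met counts, per-stratum Bernoulli bleed rates, a
group-level age profile (median, fraction over 64), a mechanism mix, a
criterion mix, INR band counts and a seed. Construction is consistent
with the rule engine by design: met records get at least one triggered
criterion (age ≥ 65 for the first `round(fraction_over_64 × n)` of them,
otherwise one criterion drawn from the mix), unmet records have every
criterion negative, which forces their age below 65. Because anyone over
64 is automatically met, an age profile demanding more over-64 records
than the met count is rejected with an `InfeasibleSpecError` naming the
conflicting constraints.

Defaults reproduce the modelled study's structure: 1,015 patients in six
groups (52/189/4/227/37/506) with met counts (40/135/3/174/35/506),
bleed rates equal to the observed stratum rates (14/178 anticoagulated
met, 9/209 anti-platelet met, 1/67 anti-platelet unmet, 36/506
untreated), and 37 VKA INR values in bands 3/18/16. The published
group-level age margins (e.g. 95% of DOAC patients over 64) are
internally inconsistent with the met counts under the age-≥65 criterion;
the defaults therefore rescale the over-64 fractions into the met stratum
(e.g. DOAC: round(0.95 × 135)/189 ≈ 68% of the group), keeping the
generator feasible and rule-consistent. Bleeding depends only on the
stratum — no covariate-dependent risk, no time-to-CT or follow-up
logistics — so passing tests demonstrate calibration of the analysis
machinery, not realism of patient-level correlations in real data.

`reference_cohort()` is the deterministic fixture: it reproduces every
published margin exactly (group and met counts, the 14/9+1/36 bleed
allocation, INR bands including the observed extremes 1.2 and 6.6, one
neurosurgery, zero deaths, 20 patients unreached at follow-up) and fills
everything below the margins — individual ages, sexes, mechanisms,
indications, the within-category bleed split (4 VKA / 9 DOAC / 1 heparin)
— by fixed round-robin cycles, so it is bit-identical across runs and
platforms. Individual INR values are fixed representatives per band
rather than draws from an invented distribution.

## The Bayesian engine

Model: `k ~ Binomial(n, p)`, `p ~ Uniform(0, 1)`; the log-posterior is
`k log p + (n−k) log(1−p)` on the unit interval, −∞ outside, with
`0·log 0 = 0` at the boundary.

Sampler: symmetric Normal random-walk Metropolis–Hastings on `p`.
Proposals outside [0, 1] have zero prior density and are rejected.
The chain starts at the conjugate posterior mean `(k+1)/(n+2)`, runs
`burn_in = 5,000` discarded steps and keeps the next
`iterations = 40,000` states. The default proposal standard deviation is
`2.4 ×` the conjugate posterior standard deviation — the classic scaling
for a univariate random walk — which gives acceptance rates around
0.3–0.45 for every stratum size in this analysis (the healthy band is
taken as 0.1–0.7; pass `proposal_scale` to retune). The sampler never
calls the conjugate quantile function; `beta_posterior_quantiles`
(deterministic inversion of the regularised incomplete beta via
`scipy.stats.beta.ppf`) exists purely as the accuracy oracle, and the
test suite holds the sampler to ±0.01 absolute agreement on the
2.5/50/97.5% quantiles at default length.

Comparisons: per-stratum chains with seeds split deterministically from
one master seed via `numpy.random.SeedSequence.spawn`, so a whole study
report is a pure function of (cohort, seed). Intervals are equal-tailed
empirical 2.5%–97.5% quantiles (the reproducible order-statistic choice;
highest-density intervals would be slightly shorter but estimator-
dependent). `P(p₁ > p₂)` is the fraction of paired draws with
`p₁ > p₂`; relative-risk draws are the elementwise ratio with the
first-named group in the numerator, summarised by median and equal-tailed
95% interval.

### Convergence diagnostics

*Geweke*: for a ladder of 20 start fractions over the first half of the
chain, the mean of the first 10% of the remaining draws is compared with
the mean of the final 50%, standardised by spectral variance estimates at
frequency zero. The spectral variance uses non-overlapping batch means
with batch length `⌊m^0.6⌋` (longer than the usual `√m` to reduce the
downward bias on autocorrelated segments). Stationary chains give |z|
fluctuating around zero; drifting chains give large |z| at early starts.

*Raftery–Lewis* (for estimating the posterior `q`-quantile to ±`r` with
probability `s`; defaults q = 0.025, r = 0.005, s = 0.95): the chain is
reduced to the binary indicator of lying at or below the empirical
`q`-quantile, thinned by increasing factors until a first-order Markov
chain fits better than a second-order one (G² with BIC penalty), and the
fitted two-state transition probabilities give the required burn-in
(ε = 0.001 convergence of the marginal) and run length. The
independent-sampling lower bound is `n_min = ⌈z²_{(1+s)/2} q(1−q)/r²⌉ =
3,746` at the defaults.

The convergence gate is deliberately strict: a chain "converges" only if
*all* 20 ladder z-scores satisfy |z| < 2 and the kept length reaches the
Raftery–Lewis requirement. With 20 correlated z-scores per chain this
flags a healthy chain now and then (and genuinely flags the 0-event
strata, whose indicator chains are sticky); failure adds a warning to the
report and the analysis proceeds — diagnostics here are inspection aids,
not gatekeepers.

## Exact test and sample size

`fisher_exact_two_tail` enumerates every 2×2 table with the observed
margins, computing hypergeometric point probabilities from log-factorials
(`gammaln`) and summing in log space. Two two-sided conventions:
*point-probability* (default) includes every table whose point
probability is at most the observed one, with a relative tie tolerance of
1e-7; *doubling* doubles the smaller tail, capped at 1. The default
matches `scipy.stats.fisher_exact` to 1e-9 relative across an exhaustive
small-table sweep plus random tables up to N = 200. For this study's
headline table (23/387 vs 1/122) the conventions give 0.0146 and 0.0211
— they disagree because an opposite-tail table is nearly tied with the
observed one — so the study report always flags which convention it used.
A degenerate table (an all-zero row or column) returns p = 1 with a
warning. The wording that motivated this operation conflated a t-test
with the exact test; only the exact test is implemented, as the t-test
adds nothing on binary outcomes.

`sample_size_proportion` is the margin-of-error formula
`⌈z² p₀(1−p₀)/d²⌉`; at (p₀ = 0.05, d = 0.02, 95%) it gives 457 per group
and a planned recruitment of 914. The design's accompanying "80% power"
phrase is not operative in this formula and is intentionally not
modelled; no two-proportion power analysis is provided.

## The study pipeline

`run_study` builds the six pre-specified comparisons — treated met vs
treated not-met; treated met vs untreated (all untreated patients are met
by the inclusion rule); anti-platelet met vs not-met; anticoagulant met
vs not-met; anticoagulant met vs anti-platelet met; VKA vs DOAC (heparin,
nested under anticoagulants elsewhere, is excluded here) — and attaches
to each a `ComparisonResult`, an exact-test p and per-chain diagnostics.
An empty stratum skips its comparison with an explicit flag. Proportions
and interval bounds are presented at one decimal percentage point and
p-values at three decimals; the JSON report keeps full precision.

## Known limitations and unreconstructible published values

The published subgroup credible intervals (4.0–9.1% / 1.0–4.9% for the
treated met/not-met strata, 4.8–13.1% / 1.0–6.3% for anti-platelets,
2.2–8.0% / 1.1–6.2% for anticoagulants) cannot be recovered from the
published counts under any standard interval — e.g. 23/387 gives
4.0–8.8% — and the anti-platelet met-vs-not-met p of 0.013 is likewise
irreproducible from 9/209 vs 1/55 (≈ 0.69 under any convention); the
counts actually used are unknowable from the printed tables. The pipeline
therefore reports its own intervals and p-values for the same strata and
asserts only the qualitative verdicts: overlap for therapy-vs-none,
anticoagulant-vs-anti-platelet and VKA-vs-DOAC, and a higher bleeding
probability among treated CCHR-met patients. The headline p = 0.023 is
bracketed by the two two-sided conventions' sensitivity rather than
asserted exactly.

Problem sizes: the test suite runs chains at the full default length
(40,000 + 5,000) for the conjugacy and coverage checks (500 replicates at
p = 0.06, n = 387), an exhaustive exact-test sweep for N ≤ 11 plus 600
random tables with N ≤ 200, and reduced chains (2,000–8,000 draws) where
only plumbing is under test. The false-difference check uses 12 replicate
cohorts at equal bleed rates with 4,000-draw chains.
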