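# Methods

`plysim` is a static microsimulation pipeline for projecting the indirect
costs of arthritis through lost productive life years (PLYs) in the
Australian population aged 45–64, exercised entirely on a synthetic-data
generator that emulates the statistical structure of the confidential
inputs such a model would normally consume (a national disability survey,
a tax–transfer microsimulation snapshot, demographic projections).

A person has a *lost PLY* in a given year when they are out of the labour
force because of their own ill-health and their main chronic condition is
arthritis or a related disorder (ICD-10 categories M00–M19, compared on
the three-character category). Five analysis groups are costed: full-time
and part-time workers with and without arthritis, and the lost-PLY group;
the unemployed, other non-participants and ill-health non-participants
with other conditions complete the population but are not separately
costed. All money is weekly AU$ at real 2013 prices unless stated.

## Pipeline

1. **Generate** a survey of `n_records` people (default 25,104 over two
   pooled survey years, weighted to 5,945,000 people in 2015) and an
   independent donor pool carrying weekly economic profiles.
2. **Impute** a profile onto every survey person by exact-cell hot-deck
   matching on ten categorical variables (labour-force status,
   income-unit type, income quintile, Age-Pension and
   disability-pension receipt, sex, age band, hours band, education,
   home ownership). Ties are broken by a seeded uniform draw; empty
   cells fall back by dropping variables one at a time.
3. **Project** to 2015/2020/2025/2030: monetary amounts are uprated at
   compound real growth (income and tax 1 %/yr, welfare 0 %/yr, base
   year 2013), and survey weights are calibrated to projection-year
   benchmarks by generalized-regression (GREG) calibration.
4. **Cost**: weighted group summaries; covariate-adjusted median gaps
   versus full-time workers without arthritis; counterfactual
   destination probabilities; national annual lost income, extra
   welfare and lost tax with bootstrap CIs.
5. **GDP**: missing workers converted to lost GDP by average-product
   attribution, and expressed as a potential percentage gain in GDP.

## Synthetic-data generator

The generator defines the study conditions; its defaults are calibrated
once to the package's 2015 scenario anchors and are not tuning knobs.

* **Group structure.** Weighted shares per year follow the scenario
  reference paths (e.g. lost-PLY share 0.91 % of 5,945,000 in 2015 →
  0.85 % of 7,130,000 in 2030). The three residual categories are set to
  unemployed 2.0 %, ill-health-other-condition 2.0 %, other
  non-participation as remainder; the 2.0 % unemployment share is the
  value that makes the full-time share of the active non-arthritis
  population equal the scenario's 71.7 % full-time destination rate.
* **Earnings** for the employed are log-normal within group, with
  group-specific log-scale SDs (0.40–0.63, set from the anchor
  mean/median skew) and multiplicative education and age effects
  (log-effects −0.35/0/+0.50 across education levels; 0/+0.02/−0.05/−0.15
  across age bands). Covariate mixes differ by group — the lost-PLY group
  is older and less educated — which is what makes the covariate-adjusted
  income gap (≈ −700/week) smaller in magnitude than the crude gap
  (≈ −985/week), as in real survey data.
* **Welfare** is rule-based, not distributional: ill-health
  non-participants mostly (85 %) receive a flat disability-pension rate
  of 311.67/week, the unemployed a flat 255/week benefit, workers an
  occasional family supplement. This reproduces the degenerate welfare
  medians (311.67 for the lost-PLY group, 0 for workers).
* **Other income** is zero-inflated log-normal (half the population
  holds none).
* **Tax** is computed by a stylised 2012-13-style annual schedule
  (progressive brackets, a low-income offset with linear phase-out, a
  1.5 % levy with a low-income phase-in, a flat deduction) applied to
  annualised non-welfare income and divided back to weeks. A
  `tax_mode="target"` option instead sets tax as a progressive power
  function of taxable income (elasticity 1.8) scaled and anchored so the
  group's weighted median tax equals its target; it exists so
  experiments can inject an exact median tax gap, which no schedule can
  guarantee, while keeping tax monotone in income as any schedule does
  (monotonicity matters: income-quintile matching then pins tax during
  imputation just as it pins income).
* **Median anchoring.** After assembly, each group's weighted median
  total income is shifted additively (earnings for workers, other income
  otherwise) onto its configured target, so generated medians match
  targets essentially exactly at any sample size. Income and tax targets
  are stored de-indexed to the 2013 base year by two years of 1 % growth,
  so uprating to 2015 reproduces the 2015 anchors; welfare targets are
  not de-indexed (zero real growth).
* **Weights** are uniform noise (±50 %) around equal weights, scaled so
  each group's weighted share and the grand total are exact.

What the generator does *not* emulate: household/family structure beyond
an income-unit label, hours-of-work heterogeneity within bands, item
non-response, wealth, the joint dependence of tax on family composition,
and any behavioural response. Passing tests therefore demonstrate that
the pipeline's statistical machinery is correct under a faithful
structural emulation — not that the synthetic absolute cost levels equal
those a confidential-data run would produce.

## Calibration (GREG)

`calibrate_weights` minimises the chi-square distance
Σ (w−d)²/d subject to X'w = T, solved through the linear system
w = d(1 + Xλ), (X'DX)λ = T − X'd (solved by least squares, so consistent
but redundant constraint blocks — e.g. several blocks each summing to
the population total — are handled). Weights breaching the configured
multiplicative bounds (default [0.1, 10]×) are clamped and the free set
re-solved until no new clamps; the result reports iterations, the
maximum relative constraint gap (tolerance 1e−6), and the clamped count.
Infeasible targets (outside bounded-weight capacity) and non-convergence
raise, the latter carrying the best achieved gap. The default benchmark
set per year: age-band × sex cell totals, all eight analysis-group
totals, and education / home-ownership / disability-pension marginals,
all derived from the same year shares so the system is exactly
consistent. The two pooled survey years are calibrated separately to
half of each target (a 50/50 pooling convention) and recombined. A
disease-trend operation can rescale arthritis-cell targets by a
multiplier, rebalancing non-arthritis cells to conserve the year total.

## Weighted median regression

Adjusted gaps come from weighted quantile regression at τ = 0.5:
minimise Σ wᵢ ρ₀.₅(yᵢ − xᵢ'β) over group contrasts (reference: full-time,
no arthritis) plus age-band, sex and education dummies. Because no
installed library fits *weighted* quantile regression, the solver is
implemented here: a Frisch–Newton primal–dual interior-point method on
the bounded LP dual, with an exact vertex certificate — once the duality
gap is small the implied basis (the p interpolated observations) is
checked for LP optimality through the complementary dual solve, and the
coefficients are recovered from a p×p system to machine precision. A
HiGHS simplex route is retained as an internal cross-check. In a
saturated groups-only design the fit reproduces differences of lower
weighted group medians exactly (generically), which is the oracle used
in tests.

Conventions: the package-wide median is the *lower weighted median*
(smallest value whose cumulative weight reaches half the total); 95 %
CIs are percentile bootstrap over case resamples with survey weights
carried, implemented as multinomial count reweighting (algebraically
identical to materialising the resample); the default is 1,000
replications, scaled to 200 in the bundled acceptance run and tests to
keep runtimes reasonable at the default problem sizes.

## National costs and GDP

Destination probabilities (full-time, part-time, unemployed absent
arthritis) are the weighted destination distribution of active
non-arthritis people, age-sex-standardised to the lost-PLY group's
profile, with the unemployment probability taken as the complement so
the three sum to one exactly. For each lost-PLY person with weight w and
current (income, welfare, tax) = (y, b, t):

* lost income  = p_ft (c_ft − y) + p_pt (c_pt − y)
* extra welfare = p_ft (b − b_ft) + p_pt (b − b_pt) + p_unemp (b − 255)
* lost tax   = p_ft (t_ft − t) + p_pt (t_pt − t) − p_unemp t

where the counterfactuals c/b/t are predicted from the median-regression
fits at the person's own age, sex and education (the unemployed
destination contributes no earnings gap and the unemployment-benefit
welfare level). National totals are weighted sums × 52 weeks, in AU$
millions; headcounts are reported to the nearest 1,000 with unrounded
values kept for arithmetic.

GDP attribution is average-product: lost GDP = GDP-per-FTE × (missing
full-time + 0.5 × missing part-time), with GDP per full-time-equivalent
worker-year 135,000 AU$ in 2015 growing at 1.17 %/yr real — an
average-labour-productivity calibration consistent with the scenario's
projected-GDP series — and the potential GDP gain is lost/projected
GDP × 100, rounded half-away-from-zero to 2 decimals. The scenario's
projected-GDP and missing-worker series are externally given inputs; the
pipeline also computes its own missing-worker counts from the lost-PLY
headcount and the destination probabilities, and keeps the two series
distinct.

## Numerical choices and degenerate inputs

* Rounding is half-away-from-zero everywhere a printed figure is
  produced (integer percent changes, two-decimal GDP gains).
* Quintile labels use weighted quantile cut points with ties falling to
  the lower quintile.
* Empty analysis groups in summaries yield null statistics with a
  warning, not an error; an empty reference group is an error.
* Collinear regression designs raise with the offending column named.
* The fallback ladder for matching can drop every variable except the
  labour-force status stratifier; exhausting it (a donor pool missing a
  whole status) raises with the unmatched key.
* Zero records is a valid generator request (empty survey, no error);
  fewer records than positive-share groups is a configuration error.

## Reproducibility

One master seed drives named substreams (generator, donors, matching,
bootstrap), so the full pipeline is bit-reproducible and stages can be
re-run in isolation. Problem sizes used by the bundled runs: the default
25,104-record survey for the pipeline and acceptance script (bootstrap
reps 200), n = 5,000 with 200 bootstrap replications × 100 replicates
for the parameter-recovery study, and 500 simulations × 1,000
replications for bootstrap-coverage checks.

## Known limitations

Absolute national cost levels depend on the synthetic scenario's shapes
(within-group dispersions, covariate mixes, tax schedule) and should be
read as structurally plausible magnitudes, not estimates for the real
population. Presenteeism, absenteeism, carer costs and arthritis
severity are out of scope. The calibration solver is "GREGWT-style"
(chi-square distance, truncation); it is verified against calibration
identities and closed-form oracles, not against the ABS implementation.
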