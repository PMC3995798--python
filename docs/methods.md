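# Methods

## Scope and frame

The package implements a static, one-year, total (not marginal) social
cost–benefit comparison of two cannabis policies for NSW in 2007 AUD: the
status quo (prohibition with cautioning/diversion) and a hypothetical
licensed, monopoly-retail legalised–regulated policy. The decision
statistic is the net social benefit (NSB), the sum of valued benefits
minus valued costs; under the Kaldor–Hicks criterion the policy with the
larger positive NSB is the more allocatively efficient. Government
revenue from retail is a transfer payment and is excluded from the default
NSB; a with-revenue variant includes the retail block. There is no
discounting (single-year frame), no currency conversion, and no
distributional weighting.

Deliberately out of scope, mirroring the exclusions of the underlying
analysis: family impacts, gang activity, alcohol substitution or
complementarity, gateway effects, international-relations consequences,
and any re-estimation of the epidemiological literature (odds ratios,
attributable fractions and NNP values enter as configuration, not as
derived quantities).

## The component ledger

Every cost or benefit is a row with a main estimate and a (low, high)
range in millions of 2007 AUD. Magnitudes are stored positive and a
five-valued `flow` field carries direction: `cost`, `benefit`,
`disbenefit` (lost benefits such as education-attainment income loss,
stigma, incarcerated wages and accident life-years), and
`revenue`/`revenue_expense` for the retail block. Three signed reporting
groups — cost, benefit (net of disbenefits) and revenue (net of retail
outflows) — reproduce the published block totals: status-quo costs 80.1
and benefits 362.7; legalised costs 90.8 against a printed 90.72/90.7 and
benefits 317.75 against a printed 318.8 (the source table's own rounding
note covers both gaps); net revenue 659.64 against a printed 659.5.
Subtotals are never stored as rows, so the published totals function as
independent checks. Where a source-specific range is missing the default
band is ±20% of the main estimate.

Validation enforces `low <= high` strictly and lets the main sit outside
the range by at most 0.05 (one printed row, parents' lost work time, is
0.1 against (0.04, 0.07)). Policy-level subtotal checks use ±0.11:
component arithmetic gives 77.5/2.6 against printed subtotals 77.6/2.5.

## Consumption shift

Use is a five-category ordered variable (none, less than monthly,
monthly, at least weekly, daily) with fixed per-category intensities:
use days/year (6, 18, 110, 365) and grams per use day (0.3, 0.4, 0.6,
1.0). These per-category mappings are not published; the values are
field-plausible representatives stated once in the default config.
Grams-per-joint detail is subsumed into grams per use day.

The legalisation scenario applies the intent question: current users
answering "increase" move up exactly one category (daily saturates);
non-users answering "try it" are allocated across user categories in
proportion to baseline user shares, adopting the destination category's
intensity. The treatment of "decrease" and current-user "not use"
answers is unspecified in the source; the default leaves them unchanged,
and a `shift_decreasers` switch moves them down one category / to none.
The shift operates on expected (fractional) counts; population is
conserved exactly.

Default intents are calibrated, not survey cross-tabs: the trier share
0.0414 = 0.44·0.086/0.914 makes prevalence rise exactly 44% (0.086 →
0.12384, printed 12.4%), and the increase share 0.10025 is solved so
total grams rise exactly 55%. The source states 55% in its methods and
52% in its discussion; the defaults calibrate to the methods figure and
the discrepancy is simply noted here. The increase share solves
`0.11 = p_inc · E[s·Δg]/E[s·g]` in closed form from the category shares
and intensities.

## Wellbeing proxy and elasticity scenario

Wellbeing from consumption is valued as eligible grams × the median
street price ($20/g), with grams consumed by under-21s or people with
cannabis use disorder excluded. The excluded shares (15.7% status quo,
39.4% legalised) are back-solved so the ledger rows 579.1 and 645.5 are
reproduced; the larger legalised exclusion reflects that much of the new
consumption accrues to dependent or under-age users whose wellbeing the
model refuses to count. Exclusion is aggregate gram-shares, not a
micro-simulation.

The elasticity scenario is a thought experiment on the legalised
wellbeing value only: quantity responds to a ±50% price change with
elasticity 0.5 and is valued at the *original* price, giving
645.5 × 1.25 = 806.9 and 645.5 × 0.75 = 484.1. No demand curve is
estimated (price is held constant everywhere else in the model).

## Harm calculators

All calculators are linear (positively homogeneous) in their exposure
argument and keep fractional expected cases internally.

* **Psychosis/schizophrenia** — additional users by stratum (heavy =
  at-least-weekly or daily) divided by stratum NNPs and costed per case.
  NNP values and per-case costs are back-solved (light = 4× heavy NNP,
  schizophrenia = 2× psychosis cost) to reproduce 55 and 24 incident
  cases and the mental-health row rising 6.2 → 7.1.
* **CUD treatment** — eligible (>5-occasion) users × CUD rate (0.20,
  SE 0.02) × an expected annual treatment-system cost per prevalent case.
  Every baseline category exceeds five occasions, so baseline eligibility
  is all current users; first-year triers reach the threshold at rate
  0.37/0.44 ≈ 0.841, giving exactly the published 37% rise in treated
  numbers. The published cost row nonetheless rises 59% (6.8 → 10.8);
  the two statements cannot both follow from one linear product, so the
  per-case costs are back-solved per policy ($70.60 / $81.84) and the
  inconsistency is absorbed there, visibly.
* **Road accidents** — expected fatalities and minor/major/permanent
  injuries are probability-per-use-day × total use days, applied as
  levels per policy (a configurable delta view is equivalent by
  linearity). Fatalities are valued at VOSLY $140k × 10 discounted
  life-years; injuries at health-system unit costs. The mortality
  valuation and health costs are reported as separate components because
  they occupy different ledger blocks. Calibration yields +1.1
  fatalities and +26 serious injuries under legalisation, inside the
  published 1–4 and 10–50 ranges.
* **Education attainment** — affected persons × 0.25 years lost × 10%
  [8–12%] earnings return per school year × $57,000 average earnings.
  The affected stocks per policy are back-solved to the rows 197.3 and
  323.0.
* **Incarceration wages** — persons × mean sentence × 2007 minimum wage
  ($27,150/yr), summed over offence types; status quo only.
* **Stigma** — 3,700 first-time convictions × $2,000 willingness to pay;
  status quo only (no such convictions under legalisation, so the
  component is absent from that ledger).

## Supply side

Operating cost is 330 shops × 2 staff × 12 h × 365 d at a composite
$28.66/staffed-hour (the wage/overhead split is unpublished; the rate is
back-solved to the 82.86 row). Revenue: 80M grams × $20/g × (1 − 0.15
leakage) = 1360; grower payments 80M × $7.72 = 617.5; net 659.64. By
default leakage reduces collected revenue only — growers are paid for
full contracted supply, because the implied farm-gate price then falls
inside the stated $5.50–8.80 band ($9.08 if leakage also cut grower
payments); a `leakage_on_grower` switch provides the alternative. Under
the default, collected net + leaked + grower payments + operating cost
equals grams × retail price exactly (revenue conservation). Public
costs: regulator = poppy-board benchmark × 1.5; enforcement and
consumer-information programs = tobacco-control per-capita benchmarks ×
population × (12.4/19.4); diversion carry-over 0.65 × 3.5 = 2.275, which
the published row rounds to 2.5 (the fixture stores the printed value and
the derivation is reported as a check). One-acre greenhouse receipts
span $39.6–63.4m across the farm-gate price band, inside the stated
$35–72m.

## Monte Carlo propagation

Components are sampled independently (no correlation structure is
stated), each from a normal distribution; draws may go negative (no
truncation by default; `truncate_at_zero` clips component draws). The
per-draw NSB is the signed sum; percentiles use linear interpolation on
order statistics (`numpy.percentile` default), and a constant trace
reports its constant as the mean to keep the degenerate case exact.
Given a seed, components consume randomness in ledger order, one
repetition-length vector each, so results are bit-reproducible and
scenario runs are draw-for-draw comparable with the base run.

The published simulation's parameterisation of the normal is not
recoverable from the published numbers. This package's default
(`sd_rule: central90`) reads each (low, high) as a central 90% interval
that fully determines the distribution: mean (low+high)/2, sd
(high−low)/(2·1.6449). The alternative `main` rule centres on the main
estimate with the same sd. The interval-centred default was chosen
because it is internally coherent (one rule, driven entirely by the
stated uncertainty) and because the with-revenue summary is arithmetically
inconsistent with main-centred sampling: the published with-revenue mean
(727.5) sits ~160m below point NSB + net revenue (886.6), while interval
centres reproduce it closely (expected ≈730). Expected means under the
default are ≈276 (status quo), ≈217 (legalised) and ≈730 (with revenue)
against published 294.6, 234.2 and 727.5 — the first two sit a few
percent below their published values under either rule, inside the
published 5–95 bands, which the test suite treats as the hard constraint.
When revenue is included, the three retail rows are sampled from their own
ranges (their interval centres sum to 513.0, matching the centre of the
published net-revenue band); the printed net-revenue triple is a subtotal
and is never sampled directly.

## Scenarios and sensitivity

A scenario is declarative: per-component scale factors (0 removes a
component, scaling main, low and high together so the sampling
distribution scales with it), low/high point overrides, an optional
elasticity adjustment to the wellbeing component, and the revenue switch.
All other components are held at their original parameterisation. The
benefit-sensitivity results follow: halving wellbeing turns both point
NSBs negative (−6.95 status quo), removing education raises the NSB by
that row's main, removing both keeps both NSBs negative. A generic
one-at-a-time low/high sweep over components is provided; published
percentage claims for individual cost rows are not asserted because they
cannot be reconciled with the table arithmetic.

## Synthetic survey generator

The generator emulates the *inputs* the aggregate analysis consumed —
one record per person with age, use category, grams per use day, use
days, CUD status, intent response and prior record — with user status
Bernoulli(0.086), categories multinomial in the default shares, grams
lognormal around the category mean (mean-preserving, σ = 0.35), fixed
use days per category, CUD Bernoulli(0.20) among >5-occasion users, and
age sampled only to support the under-21 exclusion (12% of users under
21; no survey weighting, household clustering or full demography). By
construction its aggregate expectation matches the deterministic model,
so end-to-end runs reproduce the +44%/+55% shift and the harm components
within their ledger ranges up to sampling error at n = 150,000. Passing
those checks demonstrates internal consistency of the pipeline, not
fidelity to any real survey's joint distribution.

## Problem sizes and determinism

Default problem sizes are the analysis's own: 1000 Monte Carlo
repetitions (property tests use 10,000 against the closed-form
normal-sum oracle with 4-standard-error tolerances), synthetic
populations of 100,000–150,000 records. Every stochastic path takes a
single integer seed through `numpy.random.default_rng`; identical seed
and configuration give bit-identical results.

## Known limitations

* Back-solved coefficients (NNPs, per-case costs, injury probabilities,
  affected-education stocks, excluded wellbeing shares, grams sold) are
  one of many solutions consistent with the published aggregates; they
  are documented in the config, not independently sourced.
* The published Monte Carlo means exceed both the main-estimate sums and
  the interval-centre sums; no parameterisation examined reproduces all
  three published means simultaneously, and the default reproduces the
  band structure rather than chasing any single mean.
* Several published figures are internally inconsistent (95th percentile
  372.3 vs 331.1; net revenue low/high transposed between tables;
  consumption +55% vs +52%; the elasticity-scenario NSB values); the
  package standardises on the results-table values and reports ranges in
  canonical (low, high) order.
* The comparison is total, not marginal, against a no-consumption base;
  a government contemplating the change would need a marginal analysis.
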