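# cannabis-cba

A static, one-year social **cost–benefit analysis (CBA)** comparing two
cannabis policies for New South Wales, Australia, in 2007 dollars:

* **status quo** — cannabis is illegal, with police cautioning and court
  diversion for minor possession;
* **legalised–regulated** — consumers hold a $45/year licence (age 21+),
  330 monopoly non-profit shops retail at the unchanged street price, with
  contracted growers, no advertising, and a regulatory board.

The package is aimed at drug-policy and health-economics researchers who
want the full model — component ledger, behavioural sub-models, Monte
Carlo uncertainty and sensitivity scenarios — as reusable, tested code.

## The model

Each policy is a ledger of components $b_i$ (benefits) and $c_j$ (costs),
each carrying a main estimate and a (low, high) uncertainty range in
millions of 2007 AUD. The decision statistic is the **net social benefit**

$$\mathrm{NSB} = \sum_i b_i - \sum_j c_j,$$

with government revenue treated as a transfer payment and excluded unless
the with-revenue variant is requested. Components are produced by
sub-models:

* **consumption shift** — responses to *"if cannabis were legal, would you
  (not use, decrease, try it, increase, not change use)?"* move "increase"
  respondents up one use-frequency category and allocate non-user triers
  across categories in proportion to existing use; under the packaged
  defaults prevalence rises 44% (to 12.4%) and consumption 55%, at
  constant price;
* **wellbeing proxy** — eligible grams (excluding under-21 and
  cannabis-use-disorder consumption) × the median street price;
* **harms** — psychosis/schizophrenia incidence via number-needed-to-
  prevent (NNP) denominators by heavy/light stratum, CUD treatment demand,
  road-accident burden (fatalities at the value of a statistical life
  year, injuries at health-system costs), education-attainment income loss
  (years lost × 10% [8–12%] of average earnings), incarceration wage loss
  at the minimum wage, and the willingness-to-pay value of criminal-record
  stigma;
* **market** — licensing, regulator, enforcement and consumer-information
  costs, shop operating costs, grower payments and gross revenue with 15%
  [10–20%] black-market leakage.

Uncertainty is propagated by Monte Carlo: every component is drawn
independently from a normal whose parameters are read off its (low, high)
range as a central 90% interval, and the per-draw NSB is summarised by its
mean and empirical 5th/95th percentiles over 1000 repetitions.

## Worked example

```bash
python examples/simulate_nsb.py
```

```
policy                             point    mean      p5      p95
status quo                         282.6   274.4   118.4    435.5
legalised-regulated                227.0   217.4    65.0    375.3
legalised-regulated + revenue      886.6   723.0   373.0   1041.3
```

`point` is the deterministic NSB on main estimates (e.g. status quo:
benefits 362.7 − costs 80.1 = 282.6 million); `mean`, `p5` and `p95`
summarise 1000 Monte Carlo repetitions. Both policies deliver a positive
NSB of a few hundred million dollars a year and their uncertainty bands
overlap almost completely, so neither policy is clearly more efficient;
adding net government revenue (~$660m/yr) flatters legalisation but is a
transfer, not new social value, and widens the uncertainty. The other
examples print the consumption shift, the harm components beside their
ledger rows, the retail revenue statement, the scenario analysis (halving
the wellbeing value turns both NSBs negative) and the synthetic-survey
pipeline.

## Layout

* `src/cannabis_cba/` — `ledger` (component data model, fixtures, I/O),
  `consumption`, `harms`, `market`, `nsb` (aggregation, Monte Carlo,
  scenarios), `synthetic` (survey-microdata generator), `config`, `model`
  (deterministic end-to-end pipeline);
* `src/cannabis_cba/data/` — the two ledger fixtures and the default
  configuration, with every back-solved coefficient documented in place;
* `docs/methods.md` — model assumptions, parameter provenance, numerical
  choices and limitations.
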