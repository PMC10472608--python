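# Methods

## Model and assumptions

The pipeline is a deterministic decision-analytic chain, not a fitted
statistical model: every output is an arithmetic function of its
parameters. Four stages run in sequence.

**Ledger aggregation.** Expense line items are month-dated NGN amounts
in a closed four-category scheme (personnel, vaccine transportation,
software support, other); sub-categories are free text and never drive
computation. Costs flagged as shared with the implementer's other
concurrent projects (office rent, internet and the like — which items
are shared is data, not logic) are divided equally across the
`n_projects` active projects. The analysis assumes equal apportionment
is a fair attribution and that a single reference year's expense
pattern (here 2019, the most complete reporting year) represents every
operational month. Conversion uses one fixed exchange rate
(360 NGN/USD); no exchange-rate time series is modelled.

**Annualization and inflation.** The reference monthly cost is
multiplied by each calendar year's operational months (6 + 12 + 12 + 12
= 42 for the default Jul 2015 – Dec 2018 window) and restated with
annual CPI rates (9%, 15.7%, 16.5%, 12.1% for 2015–2018; 11.4% for the
2019 reference year). "Applying the inflation rate" admits several
arithmetic readings, so the convention is an explicit enumerated
choice — `none`, `own_year`, `compound_to_end`,
`compound_to_reference`, `deflate_from_reference` — documented in
`immunocost/inflation.py`. No single convention reproduces the
published 542,132 USD total from 10,555 USD/month (candidates bracket
it: `own_year` gives 505,120, compounding to the reference year about
590,000), so the pipeline's default consumes the published total as an
explicit `total_cost_override` and reports the convention-computed
total alongside for transparency. Every downstream printed ratio
(24,983 USD per stockout point; 20.56 USD per child) is exactly
consistent with the pass-through total. No discounting or
net-present-value adjustment is performed.

**Stockout → uptake translation.** The dose-loss parameter (77
children per LGA per month per week of stockout) is a measles-derived
national average applied unchanged to all nine program vaccines — an
assumption carried as a parameter note, not logic. The LGA throughput
denominator uses national data (508,052 doses/month over 774 LGAs)
because the dose-loss estimate is national; state-level uptake may
respond differently. The translation is linear in stockout prevalence,
and cost is assumed linear in stockout reduction (no fixed-cost floor).

**Head counts and unit costs.** Under-two fraction 0.04 (half of the
8% of the population under four), coverage 0.808, population 8,000,000.
Counts round half-up to the nearest child; the incremental cost per
additional child is total cost / additional children.

## Rounding conventions (the subtle part)

All arithmetic is double precision end-to-end; rounding is a display
concern except in **paper mode**, which reproduces a printed chain in
which two intermediates were rounded before reuse:

1. the dose-reduction fraction is rounded to 3 decimals (0.46923 →
   0.469) before the uptake-reduction step — only this reproduces the
   printed 0.182 (0.469 × 0.389 = 0.18244; the unrounded fraction
   gives 0.18253 → 0.183);
2. the uptake increase is rounded to 3 decimals (0.102) before the
   head-count step — 258,560 × 0.102 = 26,373.12 → 26,373, whereas
   full precision gives ≈ 26,327.

The fraction itself is computed against the *full-precision* throughput
denominator (308 / 656.398 = 0.46923 → 0.469); using the displayed 656
would give 0.46951 → 0.470 under half-up rounding. **Exact mode**
skips both roundings. All half-way cases round away from zero
(`rounding.round_half_up`, via `decimal`), deterministic across
platforms; for the default parameters floor and nearest coincide, so
the choice is documented rather than discriminating. Fractions are
stored on the 0–1 scale; percentage points appear only at render time.

## Key parameters

| parameter | default | units | note |
|---|---|---|---|
| `monthly_category_costs_usd` | 4891 / 1628 / 2244 / 1792 | USD/month | 2019 reference breakdown; sums to 10,555 |
| `n_projects` | 14 | count | concurrent projects sharing overheads |
| `fx_naira_per_usd` | 360 | NGN/USD | fixed conversion rate |
| `inflation.rates` | 2015–2019 CPI | fraction/yr | convention `own_year` by default |
| `total_cost_override` | 542,132 | USD | pass-through headline total; `None` → convention total |
| `impact.weekly_dose_loss` | 77 | children/LGA/month/week | measles-derived |
| `impact.weeks_per_month` | 4 | weeks | month-long stockout multiplier |
| `impact.national_monthly_doses` | 508,052 | doses/month | national throughput |
| `impact.n_lgas` | 774 | count | national LGA count |
| `impact.stockout_before/after` | 0.389 / 0.172 | fraction | monthly stockout prevalence without/with the program |
| `population.total` | 8,000,000 | people | census-projected state population |
| `population.frac_under_two` | 0.04 | fraction | half of the under-four share |
| `population.coverage` | 0.808 | fraction | children with ≥ 1 vaccination |
| `budget.monthly_usd` | 39,930 | USD/month | routine-immunization budget, consumed as given (its naira derivation is not reproducible from printed inputs) |
| `reference_costs` | 101,552 / 134,622 | USD | development/capital; echoed only, added when `include_capital` |

## Sensitivity layer

One-way analysis moves one dotted-path parameter at a time to its low
and high with everything else at base, ranking parameters by induced
output range (tornado ordering); it runs in the configured mode so the
base case matches the headline figures. The probabilistic analysis
draws all parameters jointly and independently (uniform, triangular,
or truncated normal; no correlation structure is modelled because none
is estimable here) and always evaluates in exact mode — leaving the
paper-rounding steps inside a Monte Carlo would inject artificial
discreteness into the output distribution. Draws use a single seeded
`numpy` generator; the seed is recorded in the result and identical
seeds give identical summaries. Default 10,000 draws, summarized by
mean and 2.5th/97.5th percentiles.

## Synthetic ledgers

`synth.generate_ledger` emulates the *structure* of a real expense
report: per month and category it splits a target NGN total across
items with a seeded symmetric Dirichlet(5) draw, then overwrites the
last item with the exact residual so the aggregate is bit-exact at zero
noise; shared categories are pre-inflated by `n_projects` so
apportionment recovers the target. Optional noise is multiplicative
log-normal with mean one (amounts stay positive, aggregates unbiased).
What it does **not** emulate: seasonal or trending spending, category
miscoding across years (the real reports' 2015–2017 inconsistency),
lumpy one-off purchases, or any stockout time series — the stockout
effect enters as a parameter, never re-estimated. Passing tests
therefore certify the accounting arithmetic and its invariances, not
the realism of any particular expense history.

## Numerical choices and degenerate inputs

Money is IEEE double throughout; apportionment conservation and
breakdown additivity hold to 1e-12 relative, and the ledger CSV dialect
round-trips amounts exactly (shortest-repr writing,
`float_precision="round_trip"` parsing). Zero-month inputs, empty
ledgers and zero targets all produce zeros rather than errors;
genuinely undefined quantities reject loudly: zero additional children
("program produced no additional vaccinations"), non-positive exchange
rate, budget, or stockout reduction, a dose loss exceeding LGA
throughput, and unknown categories, conventions, modes, parameters or
distributions — pipeline failures carry the stage name. The test
suite's simulation sizes (10,000 PSA draws in the one calibration
check, 1,000 replicate months in the law-of-large-numbers check) were
chosen so Monte Carlo error sits well inside the asserted tolerances.

## Limitations

Beyond the modelling assumptions above: point estimates carry no
uncertainty intervals (the sensitivity layer is the uncertainty
instrument); the published total cost and monthly budget are consumed
as inputs, so the pipeline cannot detect errors in their original
derivation; and the head-count step treats uptake as homogeneous across
LGAs. Cost-effectiveness in health units (deaths averted, DALYs) is
out of scope — the chain stops at cost per additionally vaccinated
child.
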