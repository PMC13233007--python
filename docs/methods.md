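# Methods

## Model structure and assumptions

The package models the operating economics of an emergency department
(ED) over two comparison periods (or a baseline period plus hypothetical
efficiency scenarios). Revenue is taken as measured — payments received
by the hospital for ED care, excluding physician professional fees.
Costs are *not* measured; they are derived from baseline revenue through
an expected operating-margin rate `m`:

```
C = R_baseline · (1 − m)
```

This anchoring is the model's central assumption: the baseline period is
presumed to earn the margin rate typical for its payer and admission
mix. `m` is an input, not an estimate the package produces; deriving it
from payer-specific national margin data is out of scope.

Two costing frameworks project cost into the comparison period:

- **Hospital management.** `C` is split into fixed (70%), variable
  (20%), and modifiable (10%) components. Fixed costs — standby labour,
  facility, equipment, administrative overhead — are incurred to keep a
  24/7 department open and do not move with throughput. Variable costs
  (supplies, pharmaceuticals) scale with visit volume. Modifiable costs
  (contract labour, overtime, flexible staffing) scale with *care
  hours*, the product of volume and length of stay, because that is the
  workload quantity such staffing responds to. The 70/20/10 split is the
  documented default and fully overridable.
- **Public policy.** Cost is proportional to revenue at the baseline
  cost-to-revenue ratio: `cost = R′ (1 − m)`. This is the cost-to-charge
  convention of policy-level analyses. The package also offers a
  literal constant-cost-per-visit mode (`policy_mode=
  "constant_cost_per_visit"`), which differs from the proportional mode
  whenever revenue per visit changes between periods; the proportional
  mode is the default because a cost-to-charge ratio applies to charges,
  not visit counts, and it is the convention the two-period comparison
  table follows.

A consequence worth stating: under the proportional policy framework the
margin rate equals `m` identically, so *no* efficiency gain can move it.
The divergence between the frameworks is the model's point, not an
artefact.

## Scenario conventions

Efficiency change `e` rescales median ED LOS to `L(1 − e)`.

- **Capacity-constrained** (demand exceeds supply): volume responds
  equally and inversely, `V′ = V(1 + e)`, with revenue per visit held
  constant, so `R′ = R(1 + e)`. The care-hours driver is then
  `(1 + e)(1 − e) = 1 − e²` — slightly below 1 for any `e ≠ 0`, and
  symmetric in ±e. We deliberately use the multiplicative `(1 + e)`
  volume response rather than exact care-hours conservation
  (`V/(1 − e)`); the two differ at second order in `e`, and the
  multiplicative form is the one consistent with the break-even figures
  the model targets.
- **Volume-stable** (demand met): `V` and `R` are unchanged; modifiable
  cost falls by the factor `e · capture`. `capture ∈ [0, 1]` (default 1)
  is the share of the care-hours reduction a hospital actually converts
  into staffing savings — reducing contract labour requires managerial
  action, so full capture is an upper bound. Public-policy cost, being
  tied to revenue, does not move in this scenario; any positive tool
  cost therefore reduces margin under that framework.

Break-even tool cost per visit is `Δmargin / V′`. A negative value
(decreased efficiency) is reported as-is and flagged as "no sustainable
tool cost", never clamped to zero. The scenario bound `|e| ≤ 0.5` is a
sanity limit; the default sweep grid is −0.10 … +0.10 in steps of 0.01
(21 points).

## Visit-level processing

Order of operations: **attribute → cap → impute → summarise**.
Imputation uses capped values, so imputed revenue can never exceed the
cap.

- *Attribution.* Admitted visits are credited
  `24 h / hospital LOS` of their whole-stay revenue, or
  `12 h / LOS` for stays under 24 h. Stays shorter than 12 h would give
  a fraction above 1; it is capped at 1 (a visit cannot be credited more
  than the stay earned). A stay of exactly 24 h takes the `24/LOS`
  branch, i.e. is credited fully. Discharged visits are credited fully.
- *Capping.* The cap is the 95th percentile (configurable) of
  non-missing attributed revenue pooled over **both** periods — one cap
  for the whole cohort. Percentile convention: linear interpolation
  between order statistics (numpy's default), with nearest-rank
  available as an option. Capping is a deliberate conservative bias:
  high-revenue outliers follow high-acuity pathways independent of
  triage efficiency.
- *Imputation.* Stratum means over (disposition × payer), pooled across
  periods. A stratum with missing values but nothing observed falls back
  to the overall mean with a logged warning; a cohort with no observed
  revenue at all is an error.
- *Summaries.* Total revenue is accumulated with `math.fsum`, so the
  period total is exact (independent of row order) to far below cent
  precision. Currency is kept at full float precision throughout;
  rounding (whole dollars, rates to 0.1%, break-evens to cents) happens
  only in the report layer.

Input validation is strict by default — unknown payer codes are rejected
with the offending row numbers; `lenient_payers` maps them to an
`other` stratum instead.

## Synthetic cohort generator

The generator emulates the statistical shape of a two-period,
~170k-visit ED billing extract so that every pipeline stage is testable
without access to hospital data. Per-visit quantities are log-normal —
the standard choice when only a median/IQR or a mean and an upper
percentile are available for a positive, right-skewed quantity.

Study-like defaults (`study_like_config()`):

| parameter | value | basis |
|---|---|---|
| visits pre / post | 81,464 / 89,259 | cohort sizes |
| ED LOS (pre) | median 311 min, σ from IQR 182–554 | published quantiles |
| ED LOS (post) | median scaled to 292 min | published median |
| revenue/visit (pre) | capped mean $1698, 95th pct $7241 | published moments |
| revenue/visit (post) | medians scaled by 1722/1698 | published post mean |
| missing revenue | 3.19%, completely at random | published rate |
| admit rate | 0.25 | typical academic-ED admission rate |
| payer mix | medicare .30 / medicaid .25 / private .35 / self-pay .10 | typical US ED payer distribution |
| stratum revenue multipliers | admit 4× discharge; payers 1.0/0.7/1.4/0.5 | plausible relative reimbursement levels |
| hospital LOS (admits) | log-normal, median 72 h, σ 0.7 | typical inpatient stay distribution |

The per-stratum revenue medians share one base scale and one log-sd;
`solve_revenue_calibration` pins these two free parameters to the two
published facts — the pooled 95th percentile ($7241, evaluated on the
pre+post mixture including the post revenue scale) and the pre-period
capped mean ($1698) — using the closed-form censored log-normal mean and
a bracketed root find. Nothing else is fitted. The published revenue SD
($1834, post-capping) is not targeted; with two free parameters only two
moments can be matched, and the achieved SD is reported by the
acceptance script rather than imposed.

For admitted visits the generator draws the *ED-attributable* revenue
from the stratum distribution and back-solves whole-stay revenue as
`attributed / f(hospital LOS)`. The published per-visit moments describe
ED-level revenue, so parametrising at that level keeps the calibration
exact; the pipeline's attribution step then recovers the drawn value.

Missingness is completely at random (MCAR). Stratum-mean imputation is
unbiased under MCAR within strata, so this is the simplest mechanism
consistent with the imputation scheme; real billing missingness is
plausibly related to disposition or payer (MAR at best), which the
generator does not emulate.

What the generator does **not** reproduce — and hence what passing tests
do not show about real data: arrival processes, boarding and queueing
dynamics, correlation between LOS and revenue within a visit, payer-mix
differences between periods, site heterogeneity, and any non-log-normal
tail behaviour. Tests against synthetic cohorts validate the *pipeline
and model arithmetic*, not the clinical attribution of efficiency gains.

Determinism: generation is a pure function of the config. One
`SeedSequence` master seed spawns per-period, per-field substreams, so
equal configs yield byte-identical CSVs and changing one field's
consumption cannot perturb another's draws.

## Numerical choices and degenerate inputs

- Percentile cap with all values equal is the identity; `percentile=1`
  disables capping.
- `margin(0, c)` returns the margin but an explicitly undefined (`None`)
  rate rather than a division error or a fabricated 0.
- Cost-share validation requires the three shares to sum to 1 within
  1e-12; cost partitions are checked to cent tolerance.
- Ratios into the HM cost function must be strictly positive; scenario
  `|e|` is capped at 0.5.
- Break-even requires positive scenario volume.

## Problem sizes

Test and acceptance runs use seeded synthetic cohorts of 60k pre + 30k
post visits (30k/31.5k for the cross-path check) — sizes chosen so
Monte-Carlo error on per-visit means sits near the 1% level, which is
the tolerance those checks assert. The aggregate model itself is
closed-form and size-independent.

## Known limitations

- The margin rate `m` is exogenous; the model cannot detect a hospital
  whose true baseline margin differs from it.
- The 70/20/10 partition is a synthesis of published cost analyses, not
  an estimate from data; institutions should override it.
- Scenario projections are static single-period extrapolations: no
  discounting, learning curves, multi-year horizons, or probabilistic
  sensitivity analysis.
- Break-even figures inherit every assumption above; they are decision
  aids, not price predictions.
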