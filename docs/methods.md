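# Methods

## Model structure

The package models a subscription (B2C) digital screening venture over a
finite horizon (default 7 years) as a deterministic ledger driven by 24
parameters, wrapped in a Monte Carlo layer.

**Funnel.** The reachable screening pool per year is the product
`adults × eligibility × IFG prevalence × undiagnosed fraction ×
participation`. With the canonical Swiss inputs the medians give
6.5M × 0.40 × 0.11 × 0.30 × 0.10 = 8,580 reachable persons/year. The pool is
treated as a renewable flow: no depletion of the undiagnosed population and
no competitive dynamics are modelled.

**Acquisition and cadence.** Year-1 paying acquisitions are
`pool × adoption rate × paid conversion × cadence factor`. The cadence
factor (default 12) reads the adoption rate as a monthly uptake opportunity
on an annually quoted funnel; at the medians it yields
8,580 × 1.5% × 40% × 12 ≈ 618 first-year users. Without it the annual
product (≈51 users) is an order of magnitude below any plausible reading of
the venture's published scale, so the monthly cadence is the only
interpretation consistent with the anchors below.

**Adoption ramp.** Acquisition grows with a concave multiplier
`m_t = 1 + γ·ln t` (γ = `adoption_ramp_strength`, default 0.85; `linear` and
`none` schedules are available). Concavity is the natural shape for a
venture whose reach compounds through channels early and saturates as the
accessible segment is absorbed. The strength was calibrated once against the
three published user anchors (639 / 2,235 / 2,917 active users in Years
1/4/7): under the cohort recursion with median churn 0.55, the Year-4 anchor
implies γ ≈ 0.81 and the Year-7 anchor γ ≈ 0.80 — mutually consistent, which
is why a single-parameter log ramp was adopted. (No linear-to-plateau
schedule can satisfy both anchors: matching Year 4 overshoots Year 7 by
~25%, and vice versa.) Within the γ band whose Monte Carlo medians stay
inside ±5% of all three anchors (≈0.75–0.87), the default 0.85 is the value
that also reproduces the published sign of the median-scenario NPV
(marginally negative). Staffing-step discontinuities make the deterministic
NPV non-monotone in γ, so this sign carries real information about the
intended schedule.

**Cohort dynamics.** `active_t = active_{t-1}(1−churn) + new_t`; new cohorts
are not churned in their first year; users are real-valued expected counts.
Customer lifetime is deliberately *not* used in the recursion (churn already
encodes retention); it enters only the LTV unit-economics diagnostic
(LTV = price × 12 × lifetime, 720 CHF at medians; LTV/CAC ≈ 3.3).

**Ledger.** Revenue = year-end actives × price × 12 (no intra-year
proration; this matches the published Year-1/Year-7 revenue identities
639 × 480 ≈ CHF 0.31M and 2,917 × 480 ≈ CHF 1.40M). Staffing uses
`max(1, ceil(active/users-per-technician))` technicians and
`max(1, ceil(technicians/technicians-per-manager))` managers — a venture is
never unstaffed, matching the published Year-1 salary base (95k + 120k).
One-time outlays (app build, CE-MDR certification) are booked in Year 1
(`upfront_cost_year: 0` removes them from the in-horizon ledger). No taxes,
depreciation, financing costs, working capital or inflation.

**Valuation.** Cash flows are end-of-year; Year 1 is discounted one period
(no separate t=0 line — launch outlays sit in the Year-1 ledger). Terminal
value is an earnings multiple (default 10×) of final-year net cash flow,
added at t = T, negative earnings passing through by default. IRR is found
by scanning (−0.999, 10] for sign changes of NPV and bisecting to 1e−8; with
several sign changes the smallest root is returned and flagged. The
vectorised Monte Carlo variant bisects between the bracket endpoints only
and is cross-checked against the scalar implementation in the tests.

**Sampling.** Each parameter is an independent triangular(min, mode=median,
max) draw — the minimal-assumption family for a three-point elicitation;
uniform and modified-PERT are available behind the same interface and were
evaluated (neither improves agreement with the published distributional
results; PERT narrows, uniform widens). One draw per parameter per
iteration, held constant across years: a pro forma "scenario" reading.
Annual redrawing was implemented and rejected during calibration — it
shrinks the outcome variance around a loss-making centre and collapses the
median IRR far below the published level. No correlations are imposed (none
are stated). Every (seed, stream label, parameter name) triple owns an
independent substream, which gives the common-random-numbers property used
throughout: pinning any parameter leaves all other draws bit-identical.

## Breakeven convention

"Breakeven in year t" is the first year the cumulative position reaches
zero, so the yearly probabilities plus P(never) sum to one exactly. Two
bases are supported:

* **operating** — plain cumulative net cash flow (this is also what the
  per-scenario `Projection.breakeven_year` always reports);
* **exit-inclusive** (default for the Monte Carlo distribution) — the
  horizon-year position additionally includes the terminal value: the
  venture has broken even at the horizon if operations plus what the
  business would fetch at the earnings multiple cover the money sunk.

The exit-inclusive default was chosen because it is the only reading that
reproduces the published distributional results without any tuning: the
modal first-breakeven year lands in Year 7 at ≈20%, the CAC-150 /
participation-10% elasticity cell lands at 67%, the best corner near 80%,
and a CHF-20 subscription never breaks even under any churn level. Under
the operating basis the same engine yields a mid-horizon mode at ≈9% and
corner cells roughly 15 points lower, none of which resemble the published
figures. Years before the horizon are identical under both bases, so the
breakeven-by-Year-5 viability criterion is unaffected by the choice.

## Viability criteria

(i) median IRR ≥ 20% over iterations with defined IRR; (ii) probability of
breakeven by Year 5 ≥ 50%; (iii) NPV > 0 at the median scenario (criterion
wording is "under median assumptions", so it is evaluated at the
deterministic median point, not as an iteration median). On the canonical
inputs the verdict pattern is: (i) passes (median IRR ≈ 42%), (ii) fails
(≈24%), (iii) fails (≈ −78k CHF).

## Sensitivity analyses

The tornado swings one parameter at a time to its min and max, others at
medians (`npv_at_median`, deterministic) or drawn with common random numbers
(`mc_median_npv`); entries are ranked by |NPV(max) − NPV(min)|, ties broken
by name. Degenerate parameters swing exactly zero. The two-way grids pin a
parameter pair on the published lattices (price {20..60} × churn
{0.40..0.70}; CAC {150..350} × participation {5,10,15}%), draw everything
else with shared substreams (2,000 iterations per cell by default, standard
error ≲1.1 points on a probability), and are monotone along each axis in the
direction economics dictates.

## What the calibrated model does and does not reproduce

With the ramp calibrated on the user anchors only, the engine reproduces,
without further adjustment: the Year-1/4/7 active-user medians and Year-7
revenue (within ~2–4%), the base-case ledger shape (losses through Year 3,
operations near breakeven from Year 4, Year-1 ≈ 0.80M vs Year-7 ≈ 1.27M
costs, cumulative ≈ −0.2 to −0.3M at the horizon), the Year-7 breakeven mode
at 20%, the 67%/≈80% favourable grid cells, the price-20 no-breakeven
column, the tornado's price dominance, κ = −0.16, and the full verdict
pattern.

It does **not** reproduce three published statistics, and the gap is
structural, not a seed or tolerance issue. The published any-horizon
breakeven probability (57%) and the published median horizon cumulative
cash flow (−0.19M) are mutually incompatible as statistics of one simulation:
cumulative paths here are non-decreasing in their late years, so the
any-horizon probability essentially equals P(cum_T ≥ 0), and a value above
50% forces a positive median. The −0.19M figure instead matches this
package's *deterministic median scenario* (−0.2 to −0.33M depending on γ),
while the iteration median sits near −0.7M because several cost-side
triangulars (CAC, salaries, app build) are right-skewed and the downside of
the wide price/churn/funnel triples is heavier than the upside. For the same
reason the iteration-median NPV is ≈ −0.4M rather than the published −127k
(the deterministic median-scenario NPV, −78k, is close to it), and the
any-horizon probability comes out near 50% rather than 57%. Every sampling
scheme we tested (annual redrawing, funnel fixed at point estimates,
uniform, PERT, conditioning on defined IRR) moves at least one other
reproduced statistic badly out of range, so the default engine keeps the
straightforward reading and these three values are reported as measured.

## Synthetic data and test scope

The package needs no external data: the canonical inputs ship as files and
the `fixtures` generators produce random valid parameter sets and rating
matrices for property tests. The generators cover the model's *parameter
space*, not real consumer behaviour — passing tests demonstrate internal
correctness (identities, recursions, distributional support, CRN coupling,
dual-implementation agreement for kappa and IRR) and faithfulness to the
published inputs, not external validity of the venture assumptions. Problem
sizes used in tests and the acceptance script are the study's own: 5,000
Monte Carlo iterations, 2,000 iterations per grid cell, a 6×3 rating
matrix; the full suite runs in a few seconds.

## Numerical choices

Users, money and probabilities are double precision throughout; ledger
identities are exact (no rounding before presentation). Percentiles use
linear interpolation of order statistics. Iterations with undefined IRR are
excluded from IRR summaries with their count reported. The headline kappa is
rounded half-away-from-zero to two decimals. Degenerate triangular triples
return their constant without consuming random state, so adding a constant
parameter never perturbs the other draws. Seeds are combined with stream and
parameter labels via CRC-32 into independent `SeedSequence` substreams.
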