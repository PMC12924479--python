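# preventure

Early-stage viability analysis for a direct-to-consumer (B2C) digital
diabetes-screening venture, built as a reusable, tested decision-modeling
package. It is aimed at health-economics and digital-health researchers who
want to stress-test a subscription business case *before* any reimbursement
pathway exists: the kind of question an early HTA or venture due-diligence
team asks.

## What it computes

**Market funnel and cohort dynamics.** The addressable pool is an
epidemiological product — adults × screening eligibility × impaired-fasting-
glucose prevalence × undiagnosed fraction × reachable participation. Yearly
acquisition converts that pool through a digital adoption rate and a paid
conversion rate (monthly cadence, ×12), grows along a concave ramp
`1 + γ·ln t`, and the paying stock follows the cohort recursion

```
active_1 = new_1,   active_t = active_{t-1}·(1 − churn) + new_t .
```

**Pro forma ledger.** Revenue is `active_t × price × 12`. Costs split into
user-scaled lines (acquisition = new users × CAC, call-center, backend),
ceiling-rule staffing (one technician per 700 users, one manager per 15
technicians, floors of one each), per-worker office costs, recurring
compliance/maintenance, and one-time launch outlays booked in Year 1.

**Uncertainty and valuation.** Each of the 24 parameters is specified as a
(median, min, max) triple and sampled from an independent triangular
distribution, one draw per iteration. 5000 iterations yield the
breakeven-year distribution (the horizon year includes the terminal exit
value, 10× final-year earnings), and NPV/IRR distributions where

```
NPV = Σ_t cf_t/(1+d)^t + 10·cf_T/(1+d)^T ,   IRR: NPV(r) = 0 .
```

**Sensitivity.** A one-way tornado of NPV and two-way elasticity heatmaps of
breakeven probability (price × churn, CAC × participation) with common
random numbers across cells.

**Agreement.** Fleiss' kappa for the six-factor innovation system-fit
ratings (structure, financing, public policy, technology, consumers,
accountability) of three expert raters on a four-point scale.

## Worked example

```bash
preventure montecarlo --out out/
```

prints (canonical config, seed 20260128, 5000 iterations):

```
INFO preventure: monte carlo: 5000 iterations, seed 20260128
INFO preventure: breakeven: p_any=0.506 p_never=0.494 modal year 7
```

and `out/summary.json` contains, among other entries:

```
p_year:  {1: 0.000, 2: 0.021, 3: 0.068, 4: 0.076, 5: 0.077, 6: 0.065, 7: 0.198}
p_never: 0.494        modal year: 7
irr_hurdle           0.4254   passed   (median IRR 42.5% ≥ 20%)
breakeven_by_year    0.2424   FAILED   (P(breakeven by Year 5) < 50%)
median_scenario_npv  -77514   FAILED   (NPV at median assumptions < 0)
```

Reading: the venture has roughly even odds (~51%) of covering its cumulative
outlays within seven years once exit value is counted, and when it does break
even it does so late — the single most likely year is Year 7 (~20%). The
median IRR across iterations (42.5%) clears a 20% venture hurdle comfortably
because the capital base is small and inflows arrive early relative to it,
yet the deterministic median scenario still has slightly negative NPV
(CHF −78k): high percentage returns on too small an absolute scale. The
venture therefore fails two of the three a-priori viability criteria — the
published verdict pattern.

The median-scenario ledger behind those numbers:

```bash
preventure project --out out/
# -> out/projection.csv: 618 users and CHF 0.30M revenue in Year 1 growing to
#    2832 users and CHF 1.36M in Year 7; cumulative cash flow CHF -0.33M.
```

Other commands: `preventure sensitivity --mode tornado` (monthly price is the
dominant NPV driver), `preventure sensitivity --mode grid --axes
cac-participation`, and `preventure kappa` (κ = −0.16 on the shipped
six-factor ratings: experts diverge more than chance, reflecting genuine
system ambiguity).

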