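# Canonical parameter inputs for the Swiss B2C digital diabetes-screening
# pro forma model.  Percent-quoted quantities are stored as fractions.
parameters:
  adult_population: {median: 6500000, min: 6500000, max: 6500000, unit: persons}
  screening_eligibility: {median: 0.40, min: 0.30, max: 0.50, unit: proportion}
  ifg_prevalence: {median: 0.11, min: 0.10, max: 0.12, unit: proportion}
  undiagnosed_fraction: {median: 0.30, min: 0.11, max: 0.80, unit: proportion}
  screening_participation: {median: 0.10, min: 0.05, max: 0.15, unit: proportion}
  adoption_rate: {median: 0.015, min: 0.005, max: 0.020, unit: proportion}
  paid_conversion: {median: 0.40, min: 0.20, max: 0.60, unit: proportion}
  churn_rate: {median: 0.55, min: 0.40, max: 0.70, unit: proportion}
  customer_lifetime_years: {median: 1.5, min: 1.0, max: 2.0, unit: years}
  cac: {median: 220, min: 150, max: 350, unit: CHF}
  price_monthly: {median: 40, min: 20, max: 60, unit: CHF/month}
  technician_per_user_ratio: {median: 700, min: 500, max: 900, unit: users/FTE}
  manager_per_technician_ratio: {median: 15, min: 10, max: 20, unit: FTE/FTE}
  technician_salary: {median: 95000, min: 85000, max: 110000, unit: CHF/year}
  manager_salary: {median: 120000, min: 100000, max: 140000, unit: CHF/year}
  office_supplies_per_worker: {median: 1200, min: 800, max: 1500, unit: CHF/year}
  office_rent_per_worker: {median: 10000, min: 8000, max: 12000, unit: CHF/year}
  call_center_per_user: {median: 20, min: 15, max: 30, unit: CHF/year}
  backend_per_user: {median: 35, min: 25, max: 45, unit: CHF/year}
  app_development: {median: 300000, min: 250000, max: 400000, unit: CHF}
  app_maintenance: {median: 50000, min: 40000, max: 60000, unit: CHF/year}
  ce_mdr_certification: {median: 20000, min: 10000, max: 30000, unit: CHF}
  revfadp_compliance: {median: 25000, min: 15000, max: 40000, unit: CHF/year}
  discount_rate: {median: 0.18, min: 0.12, max: 0.30, unit: proportion}
run:
  horizon_years: 7
  n_iterations: 5000
  terminal_multiple: 10
  seed: 20260128
  acquisition_cadence_factor: 12
  adoption_ramp_shape: log
  adoption_ramp_strength: 0.85
  breakeven_includes_terminal: true
  upfront_cost_year: 1
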