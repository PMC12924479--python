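# A-priori viability thresholds for the investment verdict.
irr_hurdle: 0.20
breakeven_year_limit: 5
breakeven_probability_threshold: 0.50
npv_threshold: 0.0
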