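# 0/1-h hs-cTnT decision-rule cut-offs (ng/L).  These are the defaults
# from the published 0/1-h algorithm literature; deployments must confirm
# them against their assay dialect.
rule_out_baseline_max: 12.0
rule_out_delta_max: 3.0
rule_in_baseline_min: 52.0
rule_in_delta_min: 5.0
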