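# One-way sensitivity bounds: accuracy/timing at +-1 SE, costs at +-20%.
parameters:
  - {name: timing.t_second_draw, low: 1.67, high: 1.73}
  - {name: timing.t_processing, low: 1.0, high: 3.0}
  - {name: accuracy.soc_sens, low: 0.659, high: 0.721}
  - {name: accuracy.soc_spec, low: 0.976, high: 0.984}
  - {name: accuracy.rule_in_out_sens, low: 0.935, high: 0.965}
  - {name: accuracy.rule_in_out_spec, low: 0.943, high: 0.957}
  - {name: costs.scale.UK, low: 0.8, high: 1.2}
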