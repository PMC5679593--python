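# Pathway timing components, hours.
# t_alt_dx omitted -> derived as soc_mean_los_nonami - soc_mean_los_ami.
t_second_draw: 1.7
t_processing: 1.0          # sample analysis + discharge protocol (expert opinion)
soc_mean_los_ami: 5.33
soc_mean_los_nonami: 6.63
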