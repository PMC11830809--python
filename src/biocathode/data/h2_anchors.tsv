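temperature_C	ph	e_anchor_V
30	4.5	-0.038
75	4.5	-0.104
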