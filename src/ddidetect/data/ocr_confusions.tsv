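# pattern_a	pattern_b	substitution_weight (symmetric)
h	n	0.5
rn	m	0.5
l	1	0.5
o	0	0.5
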