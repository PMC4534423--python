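genotype_a	genotype_b	n_cases	n_controls
GG	AA	44	110
GG	AG	221	442
GG	GG	357	577
AG	AA	47	93
AG	AG	253	383
AG	GG	403	520
AA	AA	18	14
AA	AG	78	97
AA	GG	157	153
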