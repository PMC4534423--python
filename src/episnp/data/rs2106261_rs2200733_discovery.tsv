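genotype_a	genotype_b	n_cases	n_controls
GG	CC	44	230
GG	CT	106	475
GG	TT	83	206
AG	CC	21	206
AG	CT	117	420
AG	TT	99	243
AA	CC	13	51
AA	CT	40	115
AA	TT	46	50
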