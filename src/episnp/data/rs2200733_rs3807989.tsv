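genotype_a	genotype_b	n_cases	n_controls
CC	AA	24	43
CC	AG	79	234
CC	GG	121	317
CT	AA	44	111
CT	AG	271	485
CT	GG	454	650
TT	AA	41	63
TT	AG	202	203
TT	GG	342	283
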