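genotype_a	genotype_b	n_cases	n_controls
GG	CC	131	605
GG	CT	396	1267
GG	TT	278	579
AG	CC	121	534
AG	CT	445	1202
AG	TT	319	566
AA	CC	38	128
AA	CT	144	293
AA	TT	148	141
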