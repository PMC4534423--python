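genotype_a	genotype_b	n_cases	n_controls
GG	CC	44	176
GG	CT	161	379
GG	TT	108	197
AG	CC	56	162
AG	CT	189	404
AG	TT	124	160
AA	CC	15	30
AA	CT	57	74
AA	TT	56	45
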