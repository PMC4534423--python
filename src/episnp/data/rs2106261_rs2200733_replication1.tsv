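genotype_a	genotype_b	n_cases	n_controls
GG	CC	43	199
GG	CT	129	413
GG	TT	87	176
AG	CC	44	166
AG	CT	139	378
AG	TT	96	163
AA	CC	10	47
AA	CT	47	104
AA	TT	46	46
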