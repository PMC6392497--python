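category	driver	n_lines	n_mapped
enhancer_trap	Gal4	138	96
enhancer_trap	Cre	65	15
enhancer_trap	FP	5	4
transgenic	Gal4	20	20
transgenic	Cre	0	0
transgenic	FP	36	36
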