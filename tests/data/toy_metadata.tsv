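sample_id	mouse_id	subset	genotype	file
s1	m1	wave1	control	toy_clonotypes.tsv
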