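concept_a	concept_b	weight
migraine_with_aura	migraine	3.0
migraine_with_aura	headache	2.0
migraine_with_aura	light_sensitivity	3.0
migraine_with_aura	nausea	1.0
migraine_with_aura	vomiting	1.0
mass	lung_cancer	4.0
mass	tumor	4.0
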