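concept_id	code_system	code
migraine	ICD10	G43.909
migraine	ICD10	G43.919
migraine	ICD10	G43.009
migraine	ICD10	G43.709
migraine	ICD9	346.90
migraine	ICD9	346.10
migraine_with_aura	ICD10	G43.109
migraine_with_aura	ICD9	346.00
headache	ICD10	R51
headache	ICD10	R51.9
headache	ICD9	784.0
nausea	ICD10	R11.0
nausea	ICD9	787.02
vomiting	ICD10	R11.10
vomiting	ICD9	787.03
light_sensitivity	ICD10	H53.14
light_sensitivity	ICD9	368.13
loss_of_appetite	ICD10	R63.0
loss_of_appetite	ICD9	783.0
dizziness	ICD10	R42
dizziness	ICD9	780.4
fatigue	ICD10	R53.83
fatigue	ICD9	780.79
rizatriptan	DRUG	RIZATRIPTAN
sumatriptan	DRUG	SUMATRIPTAN
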