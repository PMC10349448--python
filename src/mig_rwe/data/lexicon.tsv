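surface	concept_ids	term_type
migraine	migraine	preferred
migraines	migraine	synonym
migraine headache	migraine	synonym
migraine with aura	migraine_with_aura	preferred
headache	headache	preferred
headaches	headache	synonym
ha	headache	abbreviation
cephalalgia	headache	synonym
nausea	nausea	preferred
nauseated	nausea	synonym
nauseous	nausea	synonym
vomiting	vomiting	preferred
vomited	vomiting	synonym
emesis	vomiting	synonym
light sensitivity	light_sensitivity	preferred
photophobia	light_sensitivity	synonym
sensitivity to light	light_sensitivity	synonym
loss of appetite	loss_of_appetite	preferred
anorexia	loss_of_appetite	synonym
poor appetite	loss_of_appetite	synonym
decreased appetite	loss_of_appetite	synonym
dizziness	dizziness	preferred
dizzy	dizziness	synonym
lightheadedness	dizziness	synonym
fatigue	fatigue	preferred
fatigued	fatigue	synonym
tiredness	fatigue	synonym
exhaustion	fatigue	synonym
rizatriptan	rizatriptan	preferred
maxalt	rizatriptan	synonym
sumatriptan	sumatriptan	preferred
imitrex	sumatriptan	synonym
ma	migraine_with_aura|mass	abbreviation
mass	mass	preferred
lung cancer	lung_cancer	preferred
lung ca	lung_cancer	abbreviation
tumor	tumor	preferred
tumour	tumor	synonym
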