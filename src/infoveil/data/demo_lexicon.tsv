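surface_form	categories	source	canonical
cancer	Cancer	medical
tumor	Cancer	medical
malignant	Cancer	medical
stroke	Cardiovascular	medical
heart attack	Cardiovascular	medical
blood pressure	Cardiovascular	medical
unconscious	Cognitive	medical
attention	Cognitive	medical
inebriation	Cognitive	medical
drunk	Cognitive	colloquial	inebriation
die	Death	medical
kill	Death	medical
lost life	Death	medical
itchy	Dermatological	medical
acne	Dermatological	medical
blister	Dermatological	medical
belly	Gastrointestinal	medical
belch	Gastrointestinal	medical
vomit	Gastrointestinal	medical
puke	Gastrointestinal	colloquial	vomit
flu	Immune System	medical
common cold	Immune System	medical
allergy	Immune System	medical
injury	Injury	medical
rupture	Injury	medical
wound	Injury	medical
bruise	Injury	medical
ptsd	Mental health	medical
adhd	Mental health	medical
jittery	Mental health	medical
coma	Neurological	medical
dizzy	Neurological	medical
lightheaded	Neurological	medical
anemia	Other	medical
jaundice	Other	medical
mumps	Other	medical
painful	Pain	medical
achy	Pain	medical
cramping	Pain	medical
toxic	Poisoning	medical
poisonous	Poisoning	medical
noxious	Poisoning	medical
pregnant	Pregnancy or in utero	medical
preggers	Pregnancy or in utero	colloquial	pregnant
miscarriage	Pregnancy or in utero	medical
cough	Respiratory	medical
wheeze	Respiratory	medical
black lung	Respiratory	medical
stressed	Stress	medical
cortisol	Stress	medical
fat	Weight	medical
obese	Weight	medical
weight	Weight	medical
stoutness	Weight	medical
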