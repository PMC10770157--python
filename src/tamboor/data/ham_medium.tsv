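# Brain-simulation medium: approximate transcription of the Ham's F-12
# composition (44 metabolites, per the Human-GEM supplementary medium
# definition) plus taurine, ornithine and NH3. Metabolite ids are generic
# names; remap to a model's namespace with an id map or override the table.
# rate_rule: glucose -> glucose uptake rate; oxygen -> 1.76 umol/g/min;
# tenth_glucose -> 1/10 of the glucose rate (the 14 constrained amino
# acids, NH3 and other organic carbon sources); free -> effectively
# unconstrained (inorganic components).
metabolite_id	name	rate_rule
glucose	D-glucose	glucose
oxygen	molecular oxygen	oxygen
histidine	L-histidine	tenth_glucose
isoleucine	L-isoleucine	tenth_glucose
leucine	L-leucine	tenth_glucose
lysine	L-lysine	tenth_glucose
methionine	L-methionine	tenth_glucose
phenylalanine	L-phenylalanine	tenth_glucose
threonine	L-threonine	tenth_glucose
tryptophan	L-tryptophan	tenth_glucose
valine	L-valine	tenth_glucose
tyrosine	L-tyrosine	tenth_glucose
cysteine	L-cysteine	tenth_glucose
arginine	L-arginine	tenth_glucose
ornithine	L-ornithine	tenth_glucose
taurine	taurine	tenth_glucose
NH3	ammonia	tenth_glucose
alanine	L-alanine	tenth_glucose
asparagine	L-asparagine	tenth_glucose
aspartate	L-aspartate	tenth_glucose
glutamate	L-glutamate	tenth_glucose
glutamine	L-glutamine	tenth_glucose
glycine	glycine	tenth_glucose
proline	L-proline	tenth_glucose
serine	L-serine	tenth_glucose
biotin	biotin	tenth_glucose
choline	choline	tenth_glucose
folate	folate	tenth_glucose
inositol	myo-inositol	tenth_glucose
nicotinamide	nicotinamide	tenth_glucose
pantothenate	pantothenate	tenth_glucose
pyridoxine	pyridoxine	tenth_glucose
riboflavin	riboflavin	tenth_glucose
thiamin	thiamin	tenth_glucose
cobalamin	vitamin B12	tenth_glucose
hypoxanthine	hypoxanthine	tenth_glucose
linoleate	linoleic acid	tenth_glucose
lipoate	lipoic acid	tenth_glucose
putrescine	putrescine	tenth_glucose
pyruvate	pyruvate	tenth_glucose
thymidine	thymidine	tenth_glucose
Ca2+	calcium	free
Fe2+	ferrous iron	free
K+	potassium	free
Mg2+	magnesium	free
Pi	phosphate	free
sulfate	sulfate	free
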