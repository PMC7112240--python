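compound_id	name	role	organic
Ala	L-alanine	NEAA_fly	true
Arg	L-arginine	EAA_fly	true
Asn	L-asparagine	NEAA_fly	true
Asp	L-aspartate	NEAA_fly	true
Ca	calcium ion	metal	false
Cu	copper ion	metal	false
Cys	L-cysteine	NEAA_fly	true
Fe	iron ion	metal	false
Gln	L-glutamine	NEAA_fly	true
Glu	L-glutamate	NEAA_fly	true
Gly	glycine	NEAA_fly	true
His	L-histidine	EAA_fly	true
Ile	L-isoleucine	EAA_fly	true
Leu	L-leucine	EAA_fly	true
Lys	L-lysine	EAA_fly	true
Met	L-methionine	EAA_fly	true
Mg	magnesium ion	metal	false
Mn	manganese ion	metal	false
Phe	L-phenylalanine	EAA_fly	true
Pro	L-proline	NEAA_fly	true
Ser	L-serine	NEAA_fly	true
Thr	L-threonine	EAA_fly	true
Trp	L-tryptophan	EAA_fly	true
Tyr	L-tyrosine	NEAA_fly	true
Val	L-valine	EAA_fly	true
Zn	zinc ion	metal	false
acecoa	acecoa	other	true
acetate_buffer	acetate buffer	buffer	true
adp	adp	other	true
agar	agar	other	true
akg	akg	other	true
amp	amp	other	true
anthranilate	anthranilate	other	true
arogenate	arogenate	other	true
atp	atp	other	true
biotin	biotin	vitamin	true
cholesterol	cholesterol	sterol	true
choline	choline	NAL	true
chorismate	chorismate	other	true
co2	co2	other	true
coa	coa	other	true
e4p	e4p	other	true
folate	folate	vitamin	true
fructose	fructose	other	true
fumarate	fumarate	other	true
g3p	g3p	other	true
g6p	g6p	other	true
glucose	glucose	other	true
homocysteine	homocysteine	other	true
homoserine	homoserine	other	true
hpp	hpp	other	true
iminoaspartate	iminoaspartate	other	true
imp	imp	other	true
inosine	inosine	NAL	true
kiv	kiv	other	true
myoinositol	myo-inositol	NAL	true
nad	nad	other	true
nadh	nadh	other	true
nadp	nadp	other	true
nadph	nadph	other	true
nicotinate	nicotinate	vitamin	true
oaa	oaa	other	true
ornithine	ornithine	other	true
pantothenate	pantothenate	vitamin	true
pep	pep	other	true
phenylpyruvate	phenylpyruvate	other	true
phosphate	phosphate	other	true
ppi	ppi	other	true
pre_biotin	pre biotin	other	true
pre_folate	pre folate	other	true
pre_pantothenate	pre pantothenate	other	true
pre_riboflavin	pre riboflavin	other	true
pre_thiamine	pre thiamine	other	true
prephenate	prephenate	other	true
proton	proton	other	true
pyridoxine	pyridoxine	vitamin	true
pyridoxine_p	pyridoxine p	other	true
pyruvate	pyruvate	other	true
r5p	r5p	other	true
riboflavin	riboflavin	vitamin	true
sucrose	sucrose	sugar	true
thiamine	thiamine	vitamin	true
ump	ump	other	true
uridine	uridine	NAL	true
water	water	other	true
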