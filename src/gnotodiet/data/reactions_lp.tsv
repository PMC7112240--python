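reaction_id	ec	reversible	route	substrates	products
upt_sucrose	3.2.1.26	false	primary	sucrose	glucose;fructose
hexokinase	2.7.1.1	false	primary	glucose	g6p
glycolysis		false	primary	g6p	g3p;pep;pyruvate
ppp		false	primary	g6p	r5p;e4p
pdh	1.2.4.1	false	primary	pyruvate	acecoa
tca		false	primary	acecoa	akg;oaa;fumarate
gdh	1.4.1.4	false	primary	akg	Glu
glnA	6.3.1.2	false	primary	Glu	Gln
proBA		false	primary	Glu	Pro
argA		false	primary	Glu	ornithine
argGH	6.3.4.5	false	primary	ornithine	Arg
serA	1.1.1.95	false	primary	g3p	Ser
glyA	2.1.2.1	false	primary	Ser	Gly
hisGD		false	primary	r5p	His
aroGB		false	primary	pep;e4p	chorismate
trpE	4.1.3.27	false	primary	chorismate	anthranilate
trpAB	4.2.1.20	false	primary	anthranilate	Trp
chorismate_mutase	5.4.99.5	false	primary	chorismate	prephenate
aspA_sec	4.3.1.1	false	secondary	fumarate	Asp
ala_sec	5.1.1.1	false	secondary	pyruvate	Ala
asnB	6.3.5.4	false	primary	Asp	Asn
hom	1.1.1.3	false	primary	Asp	homoserine
thr_sec	4.2.3.1	false	secondary	homoserine	Thr
dapA		false	primary	Asp;pyruvate	Lys
tyrA	1.3.1.12	false	primary	prephenate	arogenate
tyr_from_aro	2.6.1.5	false	primary	arogenate	Tyr
phe_from_aro_sec	2.5.1.47	false	secondary	arogenate	Phe
folP		false	primary	chorismate	pre_folate
folC	6.3.2.17	false	primary	pre_folate	folate
ribBA		false	primary	r5p	pre_riboflavin
rib_last	2.5.1.9	false	primary	pre_riboflavin	riboflavin
thi_salvage	2.7.1.49	false	primary	r5p	pre_thiamine
thi_last	2.5.1.3	false	primary	pre_thiamine	thiamine
purF		false	primary	r5p	imp
inosine_syn		false	primary	imp	inosine
pyrBC		false	primary	Asp;r5p	ump
uridine_syn		false	primary	ump	uridine
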