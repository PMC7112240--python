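reaction_id	ec	reversible	route	substrates	products
upt_sucrose	3.2.1.26	false	primary	sucrose	glucose;fructose
hexokinase	2.7.1.1	false	primary	glucose	g6p
glycolysis		false	primary	g6p	g3p;pep;pyruvate
ppp		false	primary	g6p	r5p;e4p
pdh	1.2.4.1	false	primary	pyruvate	acecoa
tca		false	primary	acecoa	akg;oaa;fumarate
gdh	1.4.1.3	false	primary	akg	Glu
glnA	6.3.1.2	false	primary	Glu	Gln
proBA		false	primary	Glu	Pro
got	2.6.1.1	false	primary	oaa	Asp
asnS	6.3.5.4	false	primary	Asp	Asn
gpt	2.6.1.2	false	primary	pyruvate	Ala
serA	1.1.1.95	false	primary	g3p	Ser
shmt	2.1.2.1	false	primary	Ser	Gly
transsulfuration	4.4.1.1	false	primary	Ser;Met	Cys;homocysteine
phe_hydroxylase	1.14.16.1	false	primary	Phe	Tyr
ino1	5.5.1.4	false	primary	g6p	myoinositol
purF		false	primary	r5p	imp
inosine_syn		false	primary	imp	inosine
pyrBC		false	primary	Asp;r5p	ump
uridine_syn		false	primary	ump	uridine
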