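compound_id	concentration	unit	droppable
Arg	4.0	mM	true
His	1.9	mM	true
Ile	4.4	mM	true
Leu	5.9	mM	true
Lys	5.5	mM	true
Met	1.5	mM	true
Phe	3.0	mM	true
Thr	4.5	mM	true
Trp	1.0	mM	true
Val	5.1	mM	true
Ala	6.5	mM	true
Asn	3.0	mM	true
Asp	3.0	mM	true
Cys	0.6	mM	true
Gln	4.5	mM	true
Glu	4.6	mM	true
Gly	5.7	mM	true
Pro	3.9	mM	true
Ser	4.0	mM	true
Tyr	2.2	mM	true
biotin	0.001	mM	true
folate	0.0017	mM	true
nicotinate	0.098	mM	true
pantothenate	0.033	mM	true
pyridoxine	0.012	mM	true
riboflavin	0.013	mM	true
thiamine	0.0059	mM	true
choline	0.477	mM	true
inosine	0.65	mM	true
myoinositol	0.055	mM	true
uridine	0.71	mM	true
cholesterol	0.3	g/L	true
sucrose	17.12	g/L	true
Ca	1.0	mM	true
Cu	0.0025	mM	true
Fe	0.02	mM	true
Mg	2.0	mM	true
Mn	0.0025	mM	true
Zn	0.025	mM	true
acetate_buffer	30.0	mM	false
agar	20.0	g/L	false
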