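recognizer	cognates	dye	intensity_mean	intensity_sd	lifetime_mean	lifetime_sd
LIV	L,I,V	dye-647	3.0	0.08	1.2	0.2
YFW	Y,F,W	dye-676	2.5	0.08	2.4	0.2
AS	A,S	dye-700	2.0	0.08	3.6	0.2
NQ	N,Q	dye-730	1.5	0.08	4.8	0.2
E	E	dye-755	1.0	0.08	6.0	0.2
R	R	dye-780	0.5	0.08	7.2	0.2
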