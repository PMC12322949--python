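recognizer	residue	mean_pd_s	binding_prob
LIV	L	0.35	0.9
LIV	I	0.23	0.9
LIV	V	0.038889	0.9
YFW	Y	0.2	0.9
YFW	F	0.2	0.9
YFW	W	0.2	0.9
AS	A	0.2	0.9
AS	S	0.2	0.9
NQ	N	1.0	0.9
NQ	Q	0.2	0.9
E	E	0.2	0.9
R	R	0.2	0.9
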