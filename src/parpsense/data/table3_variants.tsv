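patient_id	gene	cdna	protein	known_class	vaf	purity	provean_score	provean_call	dann_score	dann_call	second_hit_score	second_hit_call
Ovarian #2	BRCA1	c.53T > C	p.Met18Thr	unknown				D		D	0.19	B
Ovarian #6	PALB2	c.656A > G	p.Asp219Gly	unknown				B		B	1.12	D
Ovarian #20	BRCA1	c.2744C > T	p.Ser915Phe	unknown				D		D	0.14	B
Ovarian #23	BRCA2	c.1690T > C	p.Met990Lys	unknown				D		B	0.26	B
Breast #6	BRCA1	c.2783G > T	p.Gly928Val	unknown				D		U	1.04	D
Breast #8	BRCA2	c.4860A > T	p.Leu1620Phe	unknown				D		B	0.44	B
Breast #8	RAD51D	c.328G > A	p.Asp110Asn	unknown				D		D	0.16	B
Digestive tract #1	PALB2	c.2719G > A	p.Glu907Lys	unknown				B		B	0.66	B
Digestive tract #2	BRCA1	c.2521C > T	p.Arg841Trp	unknown				D		B	1.48	D
Digestive tract #2	UIMC1	c.1690T > C	p.Tyr564His	unknown				D		D	0.91	D
Digestive tract #5	BRCA1	c.5128A > C	p.Met1710Leu	unknown				B		B	0.34	B
Digestive tract #6	BRCA1	c.5295A > C	p.Glu1786Asp	unknown				B		U	0.27	B
Digestive tract #7	BRIP1	c.3G > A	p.Met1?	unknown				U		U	0.96	D
Skin #1	PALB2	c.2431C > T	p.Pro811Ser	unknown				B		B	0.53	B
Skin #1	RAD50	c.3041A > G	p.Gln1014Arg	unknown				B		B	0.54	B
Skin #1	RAD51C	c.584C > T	p.Ala195Val	unknown				B		D	0.72	D
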