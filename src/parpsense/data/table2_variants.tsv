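patient_id	gene	cdna	protein	known_class	vaf	purity	provean_score	provean_call	dann_score	dann_call	second_hit_score	second_hit_call
Ovarian #1	BRCA1	c.798_799delTT	Ser267LysfsTer19	pathogenic
Ovarian #2	BRCA1	c.53T > C	p.Met18Thr	unknown				D		D	0.19	B
Ovarian #3	BRCA1	c.2477_2478delCA	p.Thr826ArgfsTer4	pathogenic
Ovarian #4	BRCA2	c.7617 + 1G > T		pathogenic
Ovarian #5	BRCA1	c.181T > G	p.Cys61Gly	pathogenic
Ovarian #6	PALB2	c.656A > G	p.Asp219Gly	unknown				B		B	1.12	D
Ovarian #7	BRCA2	c.3847_3848delGT	p.Val1283LysfsTer3	pathogenic
Ovarian #8	BRCA1	c.3708T > G	p.Asn1236Lys	benign
Ovarian #9	BRCA1	c.2066_2069delGTAA	p.Ser689LysfsTer11	pathogenic
Ovarian #10	BRCA1	c.3839_3843delinsAGGC	p.Ser1280_Gln1281delinsTer	pathogenic
Ovarian #11	BRCA2	c.8504C > G	p.Ser2835Ter	pathogenic
Ovarian #12	BRCA1	c.4956G > A	p.Met1652Ile	benign
Ovarian #12	BRCA2	c.9976A > T	p.Lys3326Ter	benign
Ovarian #13	BRCA1	c.349C > T	p.His117Tyr	unknown
Ovarian #13	BRCA2	c.8494G > T	p.Glu2832Ter	pathogenic
Ovarian #14	BRCA1	c.4204C > T	p.Gln1402Ter	pathogenic
Ovarian #15	BRCA1	c.4204C > T	p.Gln1402Ter	pathogenic
Ovarian #16	BRCA1	c.68_69delAG	p.Glu23ValfsTer17	pathogenic
Ovarian #17	BRCA2	c.3267_3268delGA	p.Gln1089HisfsTer9	pathogenic
Ovarian #18	BRCA1	c.191G > A	p.Cys64Tyr	pathogenic
Ovarian #19	BRCA2	c.5350_5351delAA	p.Asn1784HisfsTer2	pathogenic
Ovarian #20	BRCA1	c.2744C > T	p.Ser915Phe	unknown				D		D	0.14	B
Ovarian #21	BRCA2	c.2539A > T	p. Arg847Ter	pathogenic
Ovarian #22	ATM	c.103C > T	p.Arg35Ter	pathogenic
Ovarian #23	BRCA2	c.1690T > C	p.Met990Lys	unknown				D		B	0.26	B
Breast #1	BRCA2	c.1981_1984dup	p.Ser662Ter	pathogenic
Breast #2	BRIP1	c.2002delG	p.Glu668LysfsTer20	pathogenic
Breast #3	BRCA1	c.5341G > T	p.Glu1781Ter	pathogenic
Breast #4	BRCA2	c.7654dupA	p.Ile2552AsnfsTer2	pathogenic
Breast #4	BRCA2	c.7645_7668delTGCATAAAAATTAACAGCAAAAAT	p.Cys2549_Asn2556del	unknown
Breast #5	BRCA1	c.4251_4252delG > T	p.Leu1418ArgfsTer9	pathogenic
Breast #6	BRCA1	c.2783G > T	p.Gly928Val	unknown				D		U	1.04	D
Breast #7	BRCA1	c.3485delA	Asp1162ValfsTer48	pathogenic
Breast #8	BRCA2	c.4860A > T	p.Leu1620Phe	unknown				D		B	0.44	B
Breast #8	RAD51D	c.328G > A	p.Asp110Asn	unknown				D		D	0.16	B
Digestive tract #1	PALB2	c.2719G > A	p.Glu907Lys	unknown				B		B	0.66	B
Digestive tract #2	BRCA1	c.2521C > T	p.Arg841Trp	unknown				D		B	1.48	D
Digestive tract #2	UIMC1	c.1690T > C	p.Tyr564His	unknown				D		D	0.91	D
Digestive tract #3	CHEK2	c.349A > G	p.Arg160Gly	pathogenic
Digestive tract #4	BRCA1	c.2521C > T	p. Arg841Trp	probably_benign
Digestive tract #5	BRCA1	c.5128A > C	p.Met1710Leu	unknown				B		B	0.34	B
Digestive tract #6	BRCA1	c.5295A > C	p.Glu1786Asp	unknown				B		U	0.27	B
Digestive tract #7	BRIP1	c.3G > A	p.Met1?	unknown				U		U	0.96	D
Digestive tract #8	ATM	c.598C > T	p.Gln200Ter	pathogenic
Endometrium #1	PTEN	c.867dupA	p.Val290SerfsTer8	pathogenic
Skin #1	PALB2	c.2431C > T	p.Pro811Ser	unknown				B		B	0.53	B
Skin #1	RAD50	c.3041A > G	p.Gln1014Arg	unknown				B		B	0.54	B
Skin #1	RAD51C	c.584C > T	p.Ala195Val	unknown				B		D	0.72	D
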