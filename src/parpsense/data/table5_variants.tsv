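patient_id	gene	cdna	protein	known_class	vaf	purity	provean_score	provean_call	dann_score	dann_call	second_hit_score	second_hit_call
Niraparib #1	INPP4B	c.1381T > C	p.Phe461Leu	unknown				N		B		D
Niraparib #2	ATM	c.2578G > C	p.Asp860His	unknown				D		D		B
Niraparib #3	FANCF	c.373G > A	p.Asp125Asn	unknown				B		B		B
Niraparib #3	PALB2	c.1273G > A	p.Val425Met	unknown				B		B		D
Niraparib #3	RAD51B	c.902G > A	p.Ser301Asn	unknown				B		D		B
Niraparib #4	ATM	c.4079G > A	p.Ser1360Asn	unknown				B		B		B
Niraparib #5	BRCA2	c.9109C > G	p.Gln3037Glu	unknown				B		B		U
Niraparib #6	BRCA2	c.1181A > C	p.Glu394Ala	unknown				B		B		U
Niraparib #7	BRCA1	c.1692T > A	p.Asn564Lys	unknown				B		B		B
Niraparib #8	RAD50	c.527C > T	p.Thr176Ile	unknown				B		D		U
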