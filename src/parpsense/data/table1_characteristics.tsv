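characteristic	n	percent	median_age_or_days	min	max
age_at_olaparib_treatment	41		63	31	84
organ_ovary	23	56.2	63	43	84
organ_breast	8	19.5	62	31	83
organ_digestive_tract	8	19.5	62	50	76
organ_digestive_pancreas	5
organ_digestive_colon	2
organ_digestive_rectum	1
organ_endometrium	1	2.4	56
organ_skin	1	2.4	73
histology_adenocarcinoma	16	39.0
histology_high_grade_serous	22	53.8
histology_clear_cell	1	2.4
histology_basal_cell	1	2.4
histology_unknown	1	2.4
platinum_treated	39	92.9
platinum_pfs_days			126	30	637
platinum_pfs_lt_90_days	7	18.0
platinum_pfs_gt_90_days	32	82.0
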