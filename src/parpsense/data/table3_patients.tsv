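patient_id	site	histology	ps	treatment	platinum_response	pfs_days	pfs_event
Ovarian #2	ovary		1	olaparib	missing	240	true
Ovarian #6	ovary		1	olaparib	missing	224	true
Ovarian #20	ovary		2	olaparib	missing	368	true
Ovarian #23	ovary		1	olaparib	missing	93	true
Breast #6	breast	adenocarcinoma	1	olaparib	missing	136	true
Breast #8	breast	adenocarcinoma	2	olaparib	missing	144	true
Digestive tract #1	digestive_tract	colon	1	olaparib	missing	36	true
Digestive tract #2	digestive_tract	pancreas	3	olaparib	missing	12	true
Digestive tract #5	digestive_tract	pancreas	0	olaparib	missing	54	true
Digestive tract #6	digestive_tract	pancreas	1	olaparib	missing	12	true
Digestive tract #7	digestive_tract	pancreas	3	olaparib	missing	27	true
Skin #1	skin	basal_cell	1	olaparib	missing	210	true
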