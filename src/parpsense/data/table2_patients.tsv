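patient_id	site	histology	ps	treatment	platinum_response	pfs_days	pfs_event
Ovarian #1	ovary			olaparib	missing	1218	false
Ovarian #2	ovary		1	olaparib	missing	240	true
Ovarian #3	ovary			olaparib	missing	953	true
Ovarian #4	ovary			olaparib	missing	441	true
Ovarian #5	ovary			olaparib	missing	59	true
Ovarian #6	ovary		1	olaparib	missing	224	true
Ovarian #7	ovary			olaparib	missing	1659	false
Ovarian #8	ovary			olaparib	missing	81	true
Ovarian #9	ovary			olaparib	missing	910	true
Ovarian #10	ovary			olaparib	missing	94	true
Ovarian #11	ovary			olaparib	missing	1359	false
Ovarian #12	ovary			olaparib	missing	58	true
Ovarian #13	ovary			olaparib	missing	120	true
Ovarian #14	ovary			olaparib	missing	101	true
Ovarian #15	ovary			olaparib	missing	168	true
Ovarian #16	ovary			olaparib	missing	79	true
Ovarian #17	ovary			olaparib	missing	614	true
Ovarian #18	ovary			olaparib	missing	636	true
Ovarian #19	ovary			olaparib	missing	1	false
Ovarian #20	ovary		2	olaparib	missing	368	true
Ovarian #21	ovary			olaparib	missing	288	true
Ovarian #22	ovary			olaparib	missing	306	true
Ovarian #23	ovary		1	olaparib	missing	93	true
Breast #1	breast	adenocarcinoma		olaparib	missing	231	true
Breast #2	breast	adenocarcinoma		olaparib	missing	98	true
Breast #3	breast	adenocarcinoma		olaparib	missing	190	true
Breast #4	breast	adenocarcinoma		olaparib	missing	223	true
Breast #5	breast	adenocarcinoma		olaparib	missing	1212	false
Breast #6	breast	adenocarcinoma	1	olaparib	missing	136	true
Breast #7	breast	adenocarcinoma		olaparib	missing	116	true
Breast #8	breast	adenocarcinoma	2	olaparib	missing	144	true
Digestive tract #1	digestive_tract	colon	1	olaparib	missing	36	true
Digestive tract #2	digestive_tract	pancreas	3	olaparib	missing	12	true
Digestive tract #3	digestive_tract	pancreas		olaparib	missing	64	true
Digestive tract #4	digestive_tract	rectum		olaparib	missing	62	true
Digestive tract #5	digestive_tract	pancreas	0	olaparib	missing	54	true
Digestive tract #6	digestive_tract	pancreas	1	olaparib	missing	12	true
Digestive tract #7	digestive_tract	pancreas	3	olaparib	missing	27	true
Digestive tract #8	digestive_tract	pancreas		olaparib	missing	20	true
Endometrium #1	endometrium	clear_cell		olaparib	missing	190	true
Skin #1	skin	basal_cell	1	olaparib	missing	210	true
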