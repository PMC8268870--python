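patient_id	site	histology	ps	treatment	platinum_response	pfs_days	pfs_event
Niraparib #1	ovary	high_grade_serous	1	niraparib	missing	392	true
Niraparib #2	ovary	high_grade_serous	1	niraparib	missing	176	true
Niraparib #3	ovary	high_grade_serous	1	niraparib	missing	113	true
Niraparib #4	ovary	high_grade_serous	1	niraparib	missing	342	true
Niraparib #5	ovary	high_grade_serous	2	niraparib	missing	84	true
Niraparib #6	ovary	high_grade_serous	1	niraparib	missing	87	true
Niraparib #7	ovary	high_grade_serous	1	niraparib	missing	469	true
Niraparib #8	ovary	high_grade_serous	1	niraparib	missing	63	true
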