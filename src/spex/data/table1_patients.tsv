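patient_id	gender	age_years	size_mm	tnm_stage	location	metastasis	ca19_9	surgical_procedure
Patient_01	male	35	18	I	head	No	no abnormal	distal pancreatectomy
Patient_02	male	33	50	II	body and tail	No	no abnormal	distal pancreatectomy
Patient_03	male	26	70	II	body and tail	No	no abnormal	distal pancreatectomy
Patient_05	female	43	108	II	head	Yes	no abnormal	total pancreatectomy
Patient_07	female	30	45	II	body and tail	No	no abnormal	distal pancreatectomy
Patient_08	female	31	45	II	head	No	no abnormal	pancreaticoduodenectomy
Patient_09	female	25	50	II	body and tail	No	no abnormal	distal pancreatectomy
Patient_10	female	25	NA	II	head	No	no abnormal	pancreaticoduodenectomy
Patient_11	male	51	138	IV	body and tail	Yes	no abnormal	distal pancreatectomy
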