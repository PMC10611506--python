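sample_id	allele	patient_category	ethnicity	specimen
VGH010	DQA1*01:01:09:02	hsct_patient	API	peripheral_blood
VGH011	DQA1*01:01:09:02	hsct_donor	API	peripheral_blood
VGH012	DQA1*01:01:09:02	hsct_donor	API	peripheral_blood
VGH013	DQA1*01:01:09:02	hsct_donor	API	peripheral_blood
VGH014	DQA1*01:01:09:02	hsct_donor	CAU	peripheral_blood
VGH015	DQA1*01:01:09:02	hsct_donor	CAU	peripheral_blood
VGH016	DQA1*01:01:09:02	solid_organ_patient	API	peripheral_blood
VGH017	DQA1*05:05:16	solid_organ_patient	NAM	peripheral_blood
VGH018	DQA1*05:05:16	solid_organ_donor	NAM	peripheral_blood
VGH002	B*48:55	solid_organ_patient	API	peripheral_blood
VGH019	B*48:55	solid_organ_donor	API	peripheral_blood
VGH020	DPA1*01:03:45	solid_organ_patient	CAU	peripheral_blood
VGH021	DPA1*01:03:45	solid_organ_donor	CAU	peripheral_blood
VGH022	C*07:1041	hsct_donor	API	peripheral_blood
VGH023	C*07:1041	hsct_donor	API	peripheral_blood
VGH024	DRB1*14:249	hsct_donor	API	peripheral_blood
VGH026	DRB1*14:249	hsct_donor	API	peripheral_blood
VGH027	DRB1*14:249	solid_organ_donor	API	peripheral_blood
VGH001	A*03:452	solid_organ_patient	API	peripheral_blood
VGH003	A*26:203	solid_organ_donor	CAU	peripheral_blood
VGH004	B*15:675	disease_association	CAU	peripheral_blood
VGH005	B*48:01:12	solid_organ_patient	API	peripheral_blood
VGH029	B*56:88	solid_organ_patient	API	peripheral_blood
VGH030	C*05:277	solid_organ_donor	CAU	peripheral_blood
VGH031	C*07:1043	solid_organ_patient	API	peripheral_blood
VGH032	DPA1*01:03:38:02	hsct_donor	API	peripheral_blood
VGH033	DPA1*01:106	solid_organ_patient	NAM	peripheral_blood
VGH034	DPA1*01:136	solid_organ_donor	API	peripheral_blood
VGH035	DPA1*01:137N	hsct_patient	CAU	peripheral_blood
VGH036	DPA1*01:60	hsct_donor	API	peripheral_blood
VGH037	DPA1*02:02:13	solid_organ_donor	CAU	peripheral_blood
VGH038	DPA1*02:96	hsct_donor	CAU	peripheral_blood
VGH039	DPB1*1088:01	solid_organ_patient	API	peripheral_blood
VGH040	DQA1*01:02:15	hsct_donor	NAM	peripheral_blood
VGH041	DQA1*01:02:16	solid_organ_patient	HIS	peripheral_blood
VGH042	DQA1*01:04:08	hsct_donor	API	peripheral_blood
VGH043	DQA1*02:01:15Q	hsct_donor	CAU	peripheral_blood
VGH044	DQA1*04:01:07	solid_organ_donor	AFA	peripheral_blood
VGH045	DRB1*14:54:12	hsct_patient	CAU	peripheral_blood
VGH046	DRB5*01:130	hsct_donor	NAM	peripheral_blood
VGH047	DRB5*02:37	hsct_donor	CAU	peripheral_blood
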