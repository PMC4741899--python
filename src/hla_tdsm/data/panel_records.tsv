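recipient_id	donor_id	locus	recipient_allele	donor_allele	n_mismatch_aa	coordinate_rmsd	revised_rmsd	note
P-UPN08	Donor01	B	B*38:01	B*27:04	18	1.3510	1.3467
P-UPN08	Donor02	B	B*38:01	B*27:04	18	1.3510	1.3467
P-UPN08	Donor03	B	B*38:01	B*27:04	18	1.3510	1.3467
P-UPN08	Donor04	A	A*30:01	A*24:02	25	0.4335	0.3847
P-UPN08	Donor04	B	B*13:01	B*27:04	23	1.3272	1.3173
P-UPN08	Donor04	B	B*38:01	B*27:04	18	1.3510	1.3467
P-UPN08	Donor04	DRB1	DRB1*07:01	DRB1*12:02	19	0.3394	0.3023
P-UPN08	Donor04	DQB1	DQB1*02:01	DQB1*03:01	18	0.1445	0.1359
P-UPN06	Donor01	B	B*18:01	B*35:01	11	0.0864	0.0684
P-UPN06	Donor01	DRB1	DRB1*14:01	DRB1*04:01	13	0.1186	0.1148
P-UPN06	Donor02	B	B*18:01	B*35:01	11	0.0864	0.0684
P-UPN06	Donor02	B	B*40:01	B*15:02	19	0.5714	0.4003
P-UPN06	Donor02	DRB1	DRB1*09:01	DRB1*04:01	16	0.3754	0.3663
P-UPN06	Donor02	DRB1	DRB1*14:01	DRB1*16:01	13	0.2070	0.2008
P-UPN06	Donor03	B	B*40:01	B*15:02	19	0.5714	0.4003
P-UPN06	Donor03	DRB1	DRB1*09:01	DRB1*16:01	13	0.3933	0.3081
P-UPN06	Donor04	B	B*18:01	B*35:01	11	0.0864	0.0684
P-UPN06	Donor04	DRB1	DRB1*14:01	DRB1*04:01	13	0.1186	0.1148
P-UPN03	CBU01	A	A*33:01	A*11:01	15	0.3615	0.0930
P-UPN03	CBU01	B	B*44:03	B*44:02	1	0.0730	0.0502
P-UPN03	CBU01	DRB1	DRB1*14:01	DRB1*04:01	13	0.1186	0.1148
P-UPN03	CBU02	B	B*44:03	B*44:02	1	0.0730	0.0502
P-UPN03	CBU02	B	B*15:01	B*54:01	17	0.6973	0.2496
P-UPN03	CBU02	DRB1	DRB1*14:01	DRB1*04:01	13	0.1186	0.1148
P-UPN03	CBU03	B	B*44:03	B*44:02	1	0.0730	0.0502
P-UPN03	CBU03	B	B*15:01	B*54:01	17	0.6973	0.2496
P-UPN03	CBU03	DRB1	DRB1*11:01	DRB1*13:01	6	0.2698	0.2483
P-UPN03	CBU04	A	A*24:02	A*11:01	24	0.4273	0.3774
P-UPN03	CBU04	B	B*44:03	B*44:02	1	0.0730	0.0502
P-UPN03	CBU04	DRB1	DRB1*11:01	DRB1*15:01	11	0.2474	0.2301
P-UPN03	CBU05	B	B*15:01	B*18:01	12	0.6855	0.1941
P-UPN03	CBU05	B	B*44:03	B*40:01	18	0.5557	0.3564
P-UPN03	CBU06	A	A*24:02	A*33:01	24	0.5550	0.3899
P-UPN03	CBU06	DRB1	DRB1*11:01	DRB1*04:01	13	0.1186	0.1148	printed pair DRB1*14:01/04:01 contradicts the genotype columns; stored under the genotype-derived pair
P-UPN07	CBU01	B	B*40:06	B*40:01	8	0.1325	0.1102
P-UPN07	CBU02	B	B*40:06	B*46:01	23	0.5792	0.4151
P-UPN07	CBU02	DQB1	DQB1*05:01	DQB1*06:01	15	0.3069	0.2974
P-UPN09	CBU01	A	A*02:03	A*24:02	22	0.1628	0.1532
P-UPN09	CBU01	DRB1	DRB1*04:06	DRB1*04:05	4	0.0152	0.0149
P-UPN09	CBU02	A	A*02:03	A*02:06	4	0.1188	0.1097
P-UPN09	CBU02	B	B*38:02	B*40:06	18	0.5899	0.3556
P-UPN09	CBU02	DRB1	DRB1*15:02	DRB1*15:01	1	0.0081	0.0072
P-UPN09	CBU03	A	A*02:03	A*02:06	4	0.1188	0.1097
P-UPN09	CBU03	B	B*40:01	B*15:27	17	0.5713	0.4004
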