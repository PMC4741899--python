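pair_id	locus	recipient_allele	donor_allele	n_mismatch_aa	pockets	peptide_binding	tcr_contact	coordinate_rmsd	revised_rmsd	note
R-UPN01	A	A*11:01	A*33:01	15	A,B,C,D,E	yes	yes	0.3615	0.0930
R-UPN01	B	B*13:01	B*44:02	11	A,B,D,E,F	yes	yes	0.0976	0.0836
R-UPN01	DRB1	DRB1*15:01	DRB1*13:01	7	A,B,C,D,E	yes	yes	0.1258	0.1192
R-UPN02	A	A*24:02	A*11:01	24	A,B,C,D,E,F	yes	yes	0.4273	0.3774
R-UPN02	B	B*40:01	B*46:01	23	A,B,C,D,E,F	yes	yes	0.5812	0.4260
R-UPN02	DRB1	DRB1*11:01	DRB1*12:01	14	A,B,C,D,E	yes	no	0.1991	0.1941
R-UPN03	A	A*02:01	A*11:01	18	A,B,C,D,E,F	yes	yes	0.4155	0.3755
R-UPN04	A	A*02:01	A*33:01	17	A,B,C,D,E,F	yes	yes	0.5467	0.3807
R-UPN05	B	B*15:01	B*44:02	17	A,B,D,E,F	yes	yes	0.3769	0.3680
R-UPN06	DRB1	DRB1*04:01	DRB1*04:04	2	A,B,D	yes	no	0.0880	0.0838
R-UPN07	A	A*02:01	A*68:01	12	A,B,C,D,E,F	yes	yes	0.4734	0.4317
R-UPN08	B	B*38:01	B*39:02	8	A,B,C,F	yes	no	0.5809	0.3517
R-UPN08	DQB1	DQB1*06:01	DQB1*06:04	11	A,B,C,D,E	yes	yes	0.3044	0.2957
R-UPN09	A	A*24:02	A*02:01	20	A,B,C,D,E,F	yes	yes	0.1666	0.1472
R-UPN09	DRB1	DRB1*08:01	DRB1*16:01	9	B,C,E	yes	no	0.2283	0.2278
R-UPN10	DQB1	DQB1*03:11	DQB1*06:11	10	A,B,E	yes	yes	0.7620	0.6333
R-UPN11	B	B*40:02	B*13:01	18	B,C,F	yes	no	0.5681	0.3628
R-UPN11	DRB1	DRB1*16:01	DRB1*16:05	1	D	yes	no	0.1378	0.1366
R-UPN11	DQB1	DQB1*03:01	DQB1*03:04	1	E	yes	no	0.0090	0.0065
R-UPN12	DRB1	DRB1*12:01	DRB1*11:01	14	A,B,C,D,E	yes	no	0.1991	0.1941
R-UPN12	DQB1	DQB1*03:01	DQB1*03:02	4	B,C,E	yes	no	0.0286	0.0270
P-UPN01	A	A*31:01	A*02:07	17	A,B,C,D,E,F	yes	yes	0.4137	0.3625
P-UPN01	B	B*48:01	B*51:01	21	A,B,C,E,F	yes	yes	0.5876	0.3657
P-UPN01	DRB1	DRB1*14:01	DRB1*12:01	14	A,B,C,D,E	yes	yes	0.1545	0.1508
P-UPN01	DQB1	DQB1*05:01	DQB1*03:01	19	A,B,C,D,E	yes	yes	0.6991	0.5304
P-UPN02	A	A*24:02	A*02:07	20	A,B,C,D,E,F	yes	yes	0.1640	0.1363
P-UPN03	A	A*33:01	A*11:01	15	A,B,C,D,E	yes	yes	0.3615	0.0929	printed 0.0930 in the donor-panel table
P-UPN03	B	B*44:03	B*44:02	1	D,E	yes	no	0.0730	0.0502
P-UPN03	DRB1	DRB1*14:01	DRB1*04:01	13	A,B,C,D,E	yes	yes	0.1186	0.1148
P-UPN04	A	A*33:01	A*03:01	12	A,B,C,D,E	yes	yes	0.3619	0.0899
P-UPN04	B	B*51:01	B*35:01	13	A,C,D,E,F	yes	no	0.6636	0.3677
P-UPN05	B	B*46:01	B*38:02	24	A,B,C,D,E,F	yes	yes	0.4214	0.3567
P-UPN05	DRB1	DRB1*15:02	DRB1*16:02	4	B,D	yes	yes	0.0345	0.0241
P-UPN06	B	B*18:01	B*35:01	11	A,B,C	yes	yes	0.0864	0.0684
P-UPN06	DRB1	DRB1*14:01	DRB1*04:01	13	A,B,C,D,E	yes	yes	0.1186	0.1148
P-UPN07	B	B*40:06	B*40:01	8	C,E,F	yes	no	0.1325	0.1102
P-UPN10	A	A*24:02	A*02:05	20	A,B,C,D,E,F	yes	yes	0.1646	0.1370
P-UPN10	B	B*27:07	B*44:02	22	A,B,C,D,E,F	yes	yes	0.3292	0.3102
P-UPN11	A	A*02:01	A*30:01	18	A,B,C,D,E,F	yes	yes	0.4225	0.3820
P-UPN11	B	B*15:01	B*13:02	16	A,B,C,D,E,F	yes	yes	0.3914	0.3724
P-UPN12	A	A*11:01	A*02:01	18	A,B,C,D,E,F	yes	yes	0.4155	0.3755
P-UPN13	A	A*26:01	A*30:01	18	A,B,C,D,E,F	yes	yes	0.0850	0.0775
P-UPN13	B	B*51:01	B*13:01	16	A,B,C,E,F	yes	yes	0.2842	0.2261
P-UPN13	DRB1	DRB1*13:01	DRB1*07:01	19	A,B,C,D,E	yes	no	0.3435	0.3129
P-UPN13	DQB1	DQB1*06:01	DQB1*02:01	21	A,B,C,D,E	yes	yes	0.8049	0.6779
P-UPN14	A	A*11:01	A*26:01	11	A,B,C,D,E,F	yes	yes	0.0412	0.0403
P-UPN15	B	B*37:01	B*46:01	25	A,B,C,D,E,F	yes	yes	0.4856	0.4726
P-UPN15	DRB1	DRB1*10:01	DRB1*09:01	16	B,C,D,E	yes	no	0.3691	0.3401
P-UPN16	B	B*54:01	B*46:01	15	A,B,C,D,E,F	yes	yes	0.6756	0.2595
P-UPN17	A	A*11:01	A*02:01	18	A,B,C,D,E,F	yes	yes	0.4155	0.3755
P-UPN17	B	B*35:01	B*13:01	15	A,B,D,E,F	yes	yes	0.7462	0.3927
P-UPN18	A	A*11:03	A*01:01	13	A,B,C,D,E,F	yes	yes	0.0171	0.0143
P-UPN18	B	B*15:18	B*57:01	20	A,B,C,E,F	yes	yes	0.4572	0.2467
P-UPN18	DRB1	DRB1*03:01	DRB1*07:01	22	A,B,C,D,E	yes	yes	0.3688	0.3368
P-UPN19	DRB1	DRB1*09:01	DRB1*15:01	17	A,B,C,D,E	yes	yes	0.3889	0.3024
P-UPN19	DQB1	DQB1*03:03	DQB1*05:01	17	A,B,D,E	yes	yes	0.6986	0.5298	printed pair DQB1*03:02/05:01 contradicts the genotype columns; stored under the genotype-derived pair
P-UPN20	A	A*31:01	A*24:02	23	A,B,C,D,E,F	yes	yes	0.4511	0.3906
P-UPN20	B	B*40:06	B*51:01	18	A,B,C,E,F	yes	yes	0.5993	0.3721
P-UPN21	A	A*24:02	A*02:01	20	A,B,C,D,E,F	yes	yes	0.1666	0.1472
P-UPN22	B	B*07:05	B*13:01	28	A,B,C,D,E,F	yes	yes	0.5769	0.3870
P-UPN22	DRB1	DRB1*15:01	DRB1*07:01	16	A,B,C,D,E	yes	yes	0.3062	0.2629
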