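recipient_id	donor_id	selected	printed_total_revised_rmsd	A_1	A_2	B_1	B_2	DRB1_1	DRB1_2	DQB1_1	DQB1_2
P-UPN08	Donor01	no	1.3467	A*11:01	A*30:01	B*13:01	B*27:04	DRB1*07:01	DRB1*12:02	DQB1*02:01	DQB1*03:01
P-UPN08	Donor02	no	1.3467	A*11:01	A*30:01	B*13:01	B*27:04	DRB1*07:01	DRB1*12:02	DQB1*02:01	DQB1*03:01
P-UPN08	Donor03	no	1.3467	A*11:01	A*30:01	B*13:01	B*27:04	DRB1*07:01	DRB1*12:02	DQB1*02:01	DQB1*03:01
P-UPN08	Donor04	no	3.4869	A*11:01	A*24:02	B*27:04	B*27:04	DRB1*12:02	DRB1*12:02	DQB1*03:01	DQB1*03:01
P-UPN06	Donor01	yes	0.1832	A*11:01	A*24:02	B*35:01	B*40:01	DRB1*04:01	DRB1*09:01	DQB1*03:02	DQB1*04:01
P-UPN06	Donor02	no	1.0358	A*11:01	A*24:02	B*15:02	B*35:01	DRB1*04:01	DRB1*16:01	DQB1*03:02	DQB1*04:01
P-UPN06	Donor03	no	0.7084	A*11:01	A*11:01	B*15:02	B*18:01	DRB1*14:01	DRB1*16:01	DQB1*03:02	DQB1*04:01
P-UPN06	Donor04	no	0.1832	A*11:01	A*24:02	B*35:01	B*40:01	DRB1*04:01	DRB1*09:01	DQB1*03:02	DQB1*04:01
P-UPN03	CBU01	yes	0.2580	A*11:01	A*24:02	B*15:01	B*44:02	DRB1*04:01	DRB1*11:01	DQB1*03:01	DQB1*06:01
P-UPN03	CBU02	no	0.4146	A*24:02	A*33:01	B*44:02	B*54:01	DRB1*04:01	DRB1*11:01	DQB1*03:01	DQB1*06:01
P-UPN03	CBU03	no	0.5481	A*24:02	A*33:01	B*44:02	B*54:01	DRB1*13:01	DRB1*14:01	DQB1*03:01	DQB1*06:01
P-UPN03	CBU04	no	0.6577	A*11:01	A*33:01	B*15:01	B*44:02	DRB1*14:01	DRB1*15:01	DQB1*03:01	DQB1*06:01
P-UPN03	CBU05	no	0.5505	A*24:02	A*33:01	B*18:01	B*40:01	DRB1*11:01	DRB1*14:01	DQB1*03:01	DQB1*06:01
P-UPN03	CBU06	no	0.5047	A*33:01	A*33:01	B*15:01	B*44:03	DRB1*04:01	DRB1*14:01	DQB1*03:01	DQB1*06:01
P-UPN07	CBU01	yes	0.1102	A*02:01	A*02:03	B*13:01	B*40:01	DRB1*08:03	DRB1*12:02	DQB1*03:01	DQB1*05:01
P-UPN07	CBU02	no	0.7125	A*02:01	A*02:01	B*13:01	B*46:01	DRB1*08:03	DRB1*12:02	DQB1*03:01	DQB1*06:01
P-UPN09	CBU01	yes	0.1681	A*11:01	A*24:02	B*38:02	B*40:01	DRB1*04:05	DRB1*15:02	DQB1*03:01	DQB1*06:01
P-UPN09	CBU02	no	0.4725	A*02:06	A*11:01	B*40:01	B*40:06	DRB1*04:06	DRB1*15:01	DQB1*03:01	DQB1*06:01
P-UPN09	CBU03	no	0.5101	A*02:06	A*11:01	B*15:27	B*38:02	DRB1*04:06	DRB1*15:02	DQB1*03:01	DQB1*06:01
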