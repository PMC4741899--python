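pair_id	group	role	transplanted	A_1	A_2	B_1	B_2	DRB1_1	DRB1_2	DQB1_1	DQB1_2
R-UPN01	retrospective	recipient	yes	A*02:01	A*11:01	B*13:01	B*40:01	DRB1*12:01	DRB1*15:01	DQB1*03:01	DQB1*06:01
R-UPN01	retrospective	donor	yes	A*02:01	A*33:01	B*40:01	B*44:02	DRB1*12:01	DRB1*13:01	DQB1*03:01	DQB1*06:01
R-UPN02	retrospective	recipient	yes	A*11:01	A*24:02	B*15:01	B*40:01	DRB1*11:01	DRB1*15:01	DQB1*03:01	DQB1*05:01
R-UPN02	retrospective	donor	yes	A*11:01	A*11:01	B*15:01	B*46:01	DRB1*12:01	DRB1*15:01	DQB1*03:01	DQB1*05:01
R-UPN03	retrospective	recipient	yes	A*02:01	A*11:01	B*40:01	B*40:01	DRB1*09:01	DRB1*11:01	DQB1*03:01	DQB1*03:03
R-UPN03	retrospective	donor	yes	A*11:01	A*11:01	B*40:01	B*46:01	DRB1*09:01	DRB1*11:01	DQB1*03:01	DQB1*03:03
R-UPN04	retrospective	recipient	yes	A*01:01	A*02:01	B*13:01	B*37:01	DRB1*10:01	DRB1*16:01	DQB1*05:01	DQB1*05:01
R-UPN04	retrospective	donor	yes	A*01:01	A*33:01	B*13:01	B*37:01	DRB1*10:01	DRB1*16:01	DQB1*05:01	DQB1*05:01
R-UPN05	retrospective	recipient	yes	A*11:01	A*30:01	B*13:01	B*15:01	DRB1*13:01	DRB1*13:01	DQB1*06:01	DQB1*06:01
R-UPN05	retrospective	donor	yes	A*11:01	A*30:01	B*13:01	B*44:02	DRB1*04:06	DRB1*13:01	DQB1*03:02	DQB1*06:01
R-UPN06	retrospective	recipient	yes	A*02:01	A*33:01	B*07:02	B*40:01	DRB1*04:01	DRB1*04:01	DQB1*02:01	DQB1*03:01
R-UPN06	retrospective	donor	yes	A*02:01	A*33:01	B*07:02	B*40:01	DRB1*04:04	DRB1*04:04	DQB1*02:01	DQB1*03:01
R-UPN07	retrospective	recipient	yes	A*02:01	A*02:03	B*38:01	B*52:01	DRB1*04:01	DRB1*07:01	DQB1*02:01	DQB1*04:01
R-UPN07	retrospective	donor	yes	A*02:03	A*68:01	B*38:01	B*52:01	DRB1*04:01	DRB1*07:01	DQB1*02:01	DQB1*04:01
R-UPN08	retrospective	recipient	yes	A*02:01	A*30:01	B*38:01	B*40:01	DRB1*11:01	DRB1*15:01	DQB1*03:01	DQB1*06:01
R-UPN08	retrospective	donor	yes	A*02:01	A*30:01	B*39:02	B*40:01	DRB1*11:01	DRB1*15:01	DQB1*03:01	DQB1*06:04
R-UPN09	retrospective	recipient	yes	A*02:01	A*24:02	B*35:01	B*40:02	DRB1*08:01	DRB1*15:01	DQB1*06:01	DQB1*06:01
R-UPN09	retrospective	donor	yes	A*02:01	A*02:01	B*35:01	B*40:02	DRB1*15:01	DRB1*16:01	DQB1*05:01	DQB1*06:01
R-UPN10	retrospective	recipient	yes	A*02:01	A*11:01	B*07:02	B*15:01	DRB1*01:01	DRB1*15:01	DQB1*03:11	DQB1*05:01
R-UPN10	retrospective	donor	yes	A*02:01	A*11:01	B*07:02	B*15:01	DRB1*01:01	DRB1*15:01	DQB1*05:01	DQB1*06:11
R-UPN11	retrospective	recipient	yes	A*11:01	A*33:01	B*40:02	B*58:01	DRB1*12:01	DRB1*16:01	DQB1*03:01	DQB1*05:01
R-UPN11	retrospective	donor	yes	A*11:01	A*33:01	B*13:01	B*58:01	DRB1*12:01	DRB1*16:05	DQB1*03:04	DQB1*05:01
R-UPN12	retrospective	recipient	yes	A*02:01	A*30:01	B*13:01	B*55:01	DRB1*07:01	DRB1*12:01	DQB1*02:01	DQB1*03:01
R-UPN12	retrospective	donor	yes	A*02:01	A*30:01	B*13:01	B*55:01	DRB1*07:01	DRB1*11:01	DQB1*02:01	DQB1*03:02
P-UPN01	prospective	recipient	yes	A*11:01	A*31:01	B*46:01	B*48:01	DRB1*08:01	DRB1*14:01	DQB1*05:01	DQB1*06:01
P-UPN01	prospective	donor	yes	A*02:07	A*11:01	B*46:01	B*51:01	DRB1*08:01	DRB1*12:01	DQB1*03:01	DQB1*06:01
P-UPN02	prospective	recipient	yes	A*24:02	A*33:01	B*35:01	B*55:01	DRB1*04:01	DRB1*12:01	DQB1*02:01	DQB1*05:01
P-UPN02	prospective	donor	yes	A*02:07	A*33:01	B*35:01	B*55:01	DRB1*04:01	DRB1*12:01	DQB1*02:01	DQB1*05:01
P-UPN03	prospective	recipient	yes	A*24:02	A*33:01	B*15:01	B*44:03	DRB1*11:01	DRB1*14:01	DQB1*03:01	DQB1*06:01
P-UPN03	prospective	donor	yes	A*11:01	A*24:02	B*15:01	B*44:02	DRB1*04:01	DRB1*11:01	DQB1*03:01	DQB1*06:01
P-UPN04	prospective	recipient	yes	A*02:01	A*33:01	B*40:01	B*51:01	DRB1*04:01	DRB1*15:01	DQB1*03:02	DQB1*06:01
P-UPN04	prospective	donor	yes	A*02:01	A*03:01	B*35:01	B*40:01	DRB1*04:01	DRB1*15:01	DQB1*03:02	DQB1*06:01
P-UPN05	prospective	recipient	yes	A*02:01	A*31:01	B*46:01	B*51:01	DRB1*12:01	DRB1*15:02	DQB1*03:01	DQB1*05:01
P-UPN05	prospective	donor	yes	A*02:01	A*31:01	B*38:02	B*51:01	DRB1*12:01	DRB1*16:02	DQB1*03:01	DQB1*05:01
P-UPN06	prospective	recipient	yes	A*11:01	A*11:01	B*18:01	B*40:01	DRB1*09:01	DRB1*14:01	DQB1*03:02	DQB1*04:01
P-UPN06	prospective	donor	yes	A*11:01	A*24:02	B*35:01	B*40:01	DRB1*04:01	DRB1*09:01	DQB1*03:02	DQB1*04:01
P-UPN07	prospective	recipient	yes	A*02:01	A*02:01	B*13:01	B*40:06	DRB1*08:03	DRB1*12:02	DQB1*03:01	DQB1*05:01
P-UPN07	prospective	donor	yes	A*02:01	A*02:03	B*13:01	B*40:01	DRB1*08:03	DRB1*12:02	DQB1*03:01	DQB1*05:01
P-UPN08	prospective	recipient	no	A*11:01	A*30:01	B*13:01	B*38:01	DRB1*07:01	DRB1*12:02	DQB1*02:01	DQB1*03:01
P-UPN09	prospective	recipient	no	A*02:03	A*11:01	B*38:02	B*40:01	DRB1*04:06	DRB1*15:02	DQB1*03:01	DQB1*06:01
P-UPN10	prospective	recipient	yes	A*02:01	A*24:02	B*27:07	B*44:02	DRB1*01:01	DRB1*11:01	DQB1*03:01	DQB1*05:01
P-UPN10	prospective	donor	yes	A*02:01	A*02:05	B*44:02	B*44:02	DRB1*01:01	DRB1*11:01	DQB1*03:01	DQB1*05:01
P-UPN11	prospective	recipient	yes	A*02:01	A*11:01	B*13:01	B*15:01	DRB1*11:01	DRB1*11:01	DQB1*03:01	DQB1*03:01
P-UPN11	prospective	donor	yes	A*11:01	A*30:01	B*13:01	B*13:02	DRB1*11:01	DRB1*11:01	DQB1*03:01	DQB1*03:01
P-UPN12	prospective	recipient	yes	A*11:01	A*24:02	B*40:01	B*51:01	DRB1*04:04	DRB1*15:01	DQB1*03:02	DQB1*06:01
P-UPN12	prospective	donor	yes	A*02:01	A*24:02	B*40:01	B*51:01	DRB1*04:04	DRB1*15:01	DQB1*03:02	DQB1*06:01
P-UPN13	prospective	recipient	yes	A*02:01	A*26:01	B*15:01	B*51:01	DRB1*09:01	DRB1*13:01	DQB1*03:03	DQB1*06:01
P-UPN13	prospective	donor	yes	A*02:01	A*30:01	B*13:01	B*15:01	DRB1*07:01	DRB1*09:01	DQB1*02:01	DQB1*03:03
P-UPN14	prospective	recipient	yes	A*01:01	A*11:01	B*37:01	B*54:01	DRB1*08:01	DRB1*10:01	DQB1*05:01	DQB1*06:01
P-UPN14	prospective	donor	yes	A*01:01	A*26:01	B*37:01	B*54:01	DRB1*08:01	DRB1*10:01	DQB1*05:01	DQB1*06:01
P-UPN15	prospective	recipient	yes	A*11:01	A*24:02	B*37:01	B*40:01	DRB1*04:01	DRB1*10:01	DQB1*02:01	DQB1*05:01
P-UPN15	prospective	donor	yes	A*11:01	A*24:02	B*40:01	B*46:01	DRB1*04:01	DRB1*09:01	DQB1*02:01	DQB1*05:01
P-UPN16	prospective	recipient	yes	A*02:01	A*02:01	B*40:01	B*54:01	DRB1*08:01	DRB1*11:01	DQB1*03:01	DQB1*06:01
P-UPN16	prospective	donor	yes	A*02:01	A*02:01	B*40:01	B*46:01	DRB1*08:01	DRB1*11:01	DQB1*03:01	DQB1*06:01
P-UPN17	prospective	recipient	yes	A*11:01	A*31:01	B*35:01	B*40:02	DRB1*11:01	DRB1*13:01	DQB1*03:01	DQB1*03:01
P-UPN17	prospective	donor	yes	A*02:01	A*31:01	B*13:01	B*40:02	DRB1*11:01	DRB1*13:01	DQB1*03:01	DQB1*06:01
P-UPN18	prospective	recipient	yes	A*11:01	A*11:03	B*15:18	B*35:01	DRB1*03:01	DRB1*15:01	DQB1*02:01	DQB1*06:01
P-UPN18	prospective	donor	yes	A*01:01	A*11:01	B*35:01	B*57:01	DRB1*07:01	DRB1*15:01	DQB1*02:01	DQB1*06:01
P-UPN19	prospective	recipient	yes	A*02:01	A*02:01	B*13:01	B*46:01	DRB1*04:01	DRB1*09:01	DQB1*03:02	DQB1*03:03
P-UPN19	prospective	donor	yes	A*02:01	A*02:01	B*13:01	B*46:01	DRB1*04:01	DRB1*15:01	DQB1*03:02	DQB1*05:01
P-UPN20	prospective	recipient	yes	A*30:01	A*31:01	B*35:01	B*40:06	DRB1*09:01	DRB1*12:01	DQB1*03:01	DQB1*03:03
P-UPN20	prospective	donor	yes	A*24:02	A*30:01	B*35:01	B*51:01	DRB1*09:01	DRB1*12:01	DQB1*03:01	DQB1*03:03
P-UPN21	prospective	recipient	yes	A*02:01	A*24:02	B*39:01	B*46:01	DRB1*09:01	DRB1*12:01	DQB1*03:01	DQB1*03:03
P-UPN21	prospective	donor	yes	A*02:01	A*02:01	B*39:01	B*46:01	DRB1*09:01	DRB1*12:01	DQB1*03:01	DQB1*03:03
P-UPN22	prospective	recipient	yes	A*02:01	A*02:01	B*07:05	B*27:07	DRB1*03:01	DRB1*15:01	DQB1*02:01	DQB1*06:01
P-UPN22	prospective	donor	yes	A*02:01	A*30:01	B*13:01	B*27:07	DRB1*03:01	DRB1*07:01	DQB1*02:01	DQB1*06:01
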