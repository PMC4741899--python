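pair_id	group	role	transplanted	A_1	A_2	B_1	B_2	DRB1_1	DRB1_2	DQB1_1	DQB1_2
R-UPN01	retrospective	recipient	yes	A*02	A*11	B*13	B*60	DRB1*12	DRB1*15	DQB1*06	DQB1*07
R-UPN01	retrospective	donor	yes	A*02	A*33	B*44	B*60	DRB1*12	DRB1*13	DQB1*06	DQB1*07
R-UPN02	retrospective	recipient	yes	A*11	A*24	B*60	B*62	DRB1*11	DRB1*15	DQB1*05	DQB1*07
R-UPN02	retrospective	donor	yes	A*11	A*11	B*46	B*62	DRB1*12	DRB1*15	DQB1*05	DQB1*07
R-UPN03	retrospective	recipient	yes	A*02	A*11	B*60	B*60	DRB1*09	DRB1*11	DQB1*07	DQB1*09
R-UPN03	retrospective	donor	yes	A*11	A*11	B*46	B*60	DRB1*09	DRB1*11	DQB1*07	DQB1*09
R-UPN04	retrospective	recipient	yes	A*01	A*02	B*13	B*37	DRB1*10	DRB1*16	DQB1*05	DQB1*05
R-UPN04	retrospective	donor	yes	A*01	A*33	B*13	B*37	DRB1*10	DRB1*16	DQB1*05	DQB1*05
R-UPN05	retrospective	recipient	yes	A*11	A*30	B*13	B*62	DRB1*13	DRB1*13	DQB1*06	DQB1*06
R-UPN05	retrospective	donor	yes	A*11	A*30	B*13	B*44	DRB1*04	DRB1*13	DQB1*06	DQB1*08
R-UPN06	retrospective	recipient	yes	A*02	A*33	B*07	B*60	DRB1*04	DRB1*04	DQB1*02	DQB1*07
R-UPN06	retrospective	donor	yes	A*02	A*33	B*07	B*60	DRB1*04	DRB1*04	DQB1*02	DQB1*07
R-UPN07	retrospective	recipient	yes	A*02	A*203	B*38	B*52	DRB1*04	DRB1*07	DQB1*02	DQB1*04
R-UPN07	retrospective	donor	yes	A*203	A*68	B*38	B*52	DRB1*04	DRB1*07	DQB1*02	DQB1*04
R-UPN08	retrospective	recipient	yes	A*02	A*30	B*38	B*60	DRB1*11	DRB1*15	DQB1*06	DQB1*07
R-UPN08	retrospective	donor	yes	A*02	A*30	B*39	B*60	DRB1*11	DRB1*15	DQB1*06	DQB1*07
R-UPN09	retrospective	recipient	yes	A*02	A*24	B*35	B*61	DRB1*08	DRB1*15	DQB1*06	DQB1*06
R-UPN09	retrospective	donor	yes	A*02	A*02	B*35	B*61	DRB1*15	DRB1*16	DQB1*05	DQB1*06
R-UPN10	retrospective	recipient	yes	A*02	A*11	B*07	B*62	DRB1*01	DRB1*15	DQB1*05	DQB1*08
R-UPN10	retrospective	donor	yes	A*02	A*11	B*07	B*62	DRB1*01	DRB1*15	DQB1*05	DQB1*06
R-UPN11	retrospective	recipient	yes	A*11	A*33	B*58	B*61	DRB1*12	DRB1*16	DQB1*05	DQB1*07
R-UPN11	retrospective	donor	yes	A*11	A*33	B*13	B*58	DRB1*12	DRB1*16	DQB1*05	DQB1*07
R-UPN12	retrospective	recipient	yes	A*02	A*30	B*13	B*55	DRB1*07	DRB1*12	DQB1*02	DQB1*07
R-UPN12	retrospective	donor	yes	A*02	A*30	B*13	B*55	DRB1*07	DRB1*11	DQB1*02	DQB1*08
P-UPN01	prospective	recipient	yes	A*11	A*31	B*46	B*48	DRB1*08	DRB1*14	DQB1*05	DQB1*06
P-UPN01	prospective	donor	yes	A*02	A*11	B*46	B*51	DRB1*08	DRB1*12	DQB1*06	DQB1*07
P-UPN02	prospective	recipient	yes	A*24	A*33	B*35	B*55	DRB1*04	DRB1*12	DQB1*02	DQB1*05
P-UPN02	prospective	donor	yes	A*02	A*33	B*35	B*55	DRB1*04	DRB1*12	DQB1*02	DQB1*05
P-UPN03	prospective	recipient	yes	A*24	A*33	B*44	B*62	DRB1*11	DRB1*14	DQB1*06	DQB1*07
P-UPN03	prospective	donor	yes	A*11	A*24	B*44	B*62	DRB1*04	DRB1*11	DQB1*06	DQB1*07
P-UPN04	prospective	recipient	yes	A*02	A*33	B*51	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*08
P-UPN04	prospective	donor	yes	A*02	A*03	B*35	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*08
P-UPN05	prospective	recipient	yes	A*02	A*31	B*46	B*51	DRB1*12	DRB1*15	DQB1*05	DQB1*07
P-UPN05	prospective	donor	yes	A*02	A*31	B*38	B*51	DRB1*12	DRB1*16	DQB1*05	DQB1*07
P-UPN06	prospective	recipient	yes	A*11	A*11	B*18	B*60	DRB1*09	DRB1*14	DQB1*04	DQB1*08
P-UPN06	prospective	donor	yes	A*11	A*24	B*35	B*60	DRB1*04	DRB1*09	DQB1*04	DQB1*08
P-UPN07	prospective	recipient	yes	A*02	A*02	B*13	B*61	DRB1*08	DRB1*12	DQB1*05	DQB1*07
P-UPN07	prospective	donor	yes	A*02	A*203	B*13	B*60	DRB1*08	DRB1*12	DQB1*05	DQB1*07
P-UPN08	prospective	recipient	no	A*11	A*30	B*13	B*38	DRB1*07	DRB1*12	DQB1*02	DQB1*07
P-UPN08	prospective	donor	no	A*11	A*30	B*13	B*27	DRB1*07	DRB1*12	DQB1*02	DQB1*07
P-UPN09	prospective	recipient	no	A*203	A*11	B*38	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*07
P-UPN09	prospective	donor	no	A*11	A*24	B*38	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*07
P-UPN10	prospective	recipient	yes	A*02	A*24	B*27	B*44	DRB1*01	DRB1*11	DQB1*05	DQB1*07
P-UPN10	prospective	donor	yes	A*02	A*02	B*44	B*44	DRB1*01	DRB1*11	DQB1*05	DQB1*07
P-UPN11	prospective	recipient	yes	A*02	A*11	B*13	B*62	DRB1*11	DRB1*11	DQB1*07	DQB1*07
P-UPN11	prospective	donor	yes	A*11	A*30	B*13	B*13	DRB1*11	DRB1*11	DQB1*07	DQB1*07
P-UPN12	prospective	recipient	yes	A*11	A*24	B*51	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*08
P-UPN12	prospective	donor	yes	A*02	A*24	B*51	B*60	DRB1*04	DRB1*15	DQB1*06	DQB1*08
P-UPN13	prospective	recipient	yes	A*02	A*26	B*51	B*62	DRB1*09	DRB1*13	DQB1*06	DQB1*09
P-UPN13	prospective	donor	yes	A*02	A*30	B*13	B*62	DRB1*07	DRB1*09	DQB1*02	DQB1*09
P-UPN14	prospective	recipient	yes	A*01	A*11	B*37	B*54	DRB1*08	DRB1*10	DQB1*05	DQB1*06
P-UPN14	prospective	donor	yes	A*01	A*26	B*37	B*54	DRB1*08	DRB1*10	DQB1*05	DQB1*06
P-UPN15	prospective	recipient	yes	A*11	A*24	B*37	B*60	DRB1*04	DRB1*10	DQB1*02	DQB1*05
P-UPN15	prospective	donor	yes	A*11	A*24	B*46	B*60	DRB1*04	DRB1*09	DQB1*02	DQB1*05
P-UPN16	prospective	recipient	yes	A*02	A*02	B*54	B*60	DRB1*08	DRB1*11	DQB1*06	DQB1*07
P-UPN16	prospective	donor	yes	A*02	A*02	B*46	B*60	DRB1*08	DRB1*11	DQB1*06	DQB1*07
P-UPN17	prospective	recipient	yes	A*11	A*31	B*35	B*61	DRB1*11	DRB1*13	DQB1*07	DQB1*07
P-UPN17	prospective	donor	yes	A*02	A*31	B*13	B*61	DRB1*11	DRB1*13	DQB1*06	DQB1*07
P-UPN18	prospective	recipient	yes	A*11	A*11	B*35	B*71	DRB1*15	DRB1*17	DQB1*02	DQB1*06
P-UPN18	prospective	donor	yes	A*01	A*11	B*35	B*57	DRB1*07	DRB1*15	DQB1*02	DQB1*06
P-UPN19	prospective	recipient	yes	A*02	A*02	B*13	B*46	DRB1*04	DRB1*09	DQB1*08	DQB1*09
P-UPN19	prospective	donor	yes	A*02	A*02	B*13	B*46	DRB1*04	DRB1*15	DQB1*05	DQB1*08
P-UPN20	prospective	recipient	yes	A*30	A*31	B*35	B*61	DRB1*09	DRB1*12	DQB1*07	DQB1*09
P-UPN20	prospective	donor	yes	A*24	A*30	B*35	B*51	DRB1*09	DRB1*12	DQB1*07	DQB1*09
P-UPN21	prospective	recipient	yes	A*02	A*24	B*39	B*46	DRB1*09	DRB1*12	DQB1*07	DQB1*09
P-UPN21	prospective	donor	yes	A*02	A*02	B*39	B*46	DRB1*09	DRB1*12	DQB1*07	DQB1*09
P-UPN22	prospective	recipient	yes	A*02	A*02	B*07	B*27	DRB1*15	DRB1*17	DQB1*02	DQB1*06
P-UPN22	prospective	donor	yes	A*02	A*30	B*13	B*27	DRB1*07	DRB1*17	DQB1*02	DQB1*06
P-UPN23	prospective	recipient	no	A*02	A*11	B*54	B*60	DRB1*04	DRB1*04	DQB1*04	DQB1*07
P-UPN23	prospective	donor	no	A*02	A*11	B*54	B*60	DRB1*04	DRB1*14	DQB1*05	DQB1*07
P-UPN24	prospective	recipient	no	A*11	A*11	B*13	B*54	DRB1*08	DRB1*14	DQB1*05	DQB1*06
P-UPN24	prospective	donor	no	A*11	A*11	B*54	B*75	DRB1*08	DRB1*14	DQB1*05	DQB1*06
P-UPN25	prospective	recipient	no	A*11	A*11	B*51	B*75	DRB1*11	DRB1*12	DQB1*06	DQB1*07
P-UPN25	prospective	donor	no	A*11	A*11	B*51	B*55	DRB1*11	DRB1*14	DQB1*06	DQB1*07
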