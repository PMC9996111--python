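subject	sex	age	interval_injury_mri	interval_mri_discharge	etiology	diagnosis	drs_discharge	crsr_discharge
1	f	67	14	34	CVA	VS/UWS	5	23
2	m	24	8	45	CVA	VS/UWS	22	13
3	m	64	45	28	CVA	VS/UWS	22	4
4	f	57	9	11	CVA	MCS	17	15
5	f	72	101	28	CVA	MCS	25	5
6	m	73	16	41	CVA	VS/UWS	19	16
7	f	67	4	20	TBI	VS/UWS	9	23
8	m	37	1	42	ANOX	COMA	27	4
9	f	35	33	33	TBI	VS/UWS	21	7
10	m	60	21	10	TBI	VS/UWS	9	23
11	m	63	19	63	CVA	MCS	4	22
12	m	55	19	41	CVA	MCS	15	11
13	m	42	31	14	TBI	COMA	15	20
14	f	65	43	8	ANOX	COMA	7	23
15	m	27	287	16	TBI	VS/UWS	20	11
16	m	28	42	8	TBI	MCS	2	23
17	f	37	30	60	TBI	COMA	23	9
18	m	47	16	44	TBI	VS/UWS	7	22
19	f	66	30	28	TBI	COMA	11	23
20	f	39	34	20	CVA	COMA	11	21
21	f	52	23	27	CVA	MCS	15	21
22	m	61	35	27	CVA	COMA	14	18
23	m	61	34	34	CVA	COMA	11	23
24	m	78	50	41	ENC	COMA	15	13
25	m	44	28	26	TBI	COMA	11	21
26	f	60	26	49	CVA	COMA	22	11
27	f	69	41	59	ENC	MCS	18	11
28	f	54	30	25	TBI	VS/UWS	26	5
29	m	50	9	63	ANOX	MCS	8	22
30	f	84	26	14	TBI	COMA	21	13
31	m	16	20	12	TBI	MCS	6	23
32	m	35	19	25	LEUCO	VS/UWS	18	13
33	m	49	29	15	CVA	MCS-	6	21
34	m	72	22	13	CVA	MCS-	7	22
35	m	55	41	47	CVA	COMA	29	22
36	f	58	63	-5	CVA	VS/UWS	9	20
37	f	25	38	7	TBI	VS/UWS	11	11
38	m	73	20	37	TBI	VS/UWS	7	22
39	m	60	38	20	CVA	VS/UWS	11	22
40	m	59	43	3	ANOX	VS/UWS	23	8
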