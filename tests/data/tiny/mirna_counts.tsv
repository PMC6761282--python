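feature	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
mir-0001	100	156	86	70	79	52	57	77	149	145	70	98
mir-0002	65	168	63	118	122	83	43	122	161	59	142	97
mir-0003	26	33	25	33	72	37	56	54	57	52	38	51
mir-0004	4	16	16	12	14	29	13	9	16	18	12	22
mir-0005	169	455	143	735	229	400	826	618	1270	3441	2079	3487
mir-0006	55	113	97	80	70	48	75	57	80	83	47	77
mir-0007	6	3	11	12	7	23	18	5	20	8	13	7
mir-0008	77	74	73	42	70	57	43	44	30	45	35	51
mir-0009	57	62	60	172	72	135	247	191	308	626	525	691
mir-0010	40	43	73	62	77	56	36	54	101	77	55	41
mir-0011	7	4	5	7	9	7	3	3	5	8	3	7
mir-0012	524	442	442	619	450	288	267	209	405	260	274	313
mir-0013	190	275	217	161	176	188	153	86	171	102	107	179
mir-0014	65	101	112	64	58	54	118	80	86	142	51	158
mir-0015	14	42	26	6	49	27	70	15	29	27	14	17
mir-0016	49	67	42	65	50	49	65	55	64	41	41	55
mir-0017	458	738	428	336	717	421	529	413	354	296	456	531
mir-0018	22	53	54	44	33	25	47	20	53	50	11	39
mir-0019	38	44	60	4	12	15	8	6	17	3	4	3
mir-0020	49	112	75	95	34	64	101	83	84	118	32	127
mir-0021	6	26	16	4	6	5	5	4	3	3	0	7
mir-0022	1	3	2	4	3	4	8	4	9	4	3	5
mir-0023	106	166	172	154	121	82	353	76	195	144	97	187
mir-0024	14	22	13	7	13	10	15	7	13	8	8	25
mir-0025	34	30	42	24	23	86	27	66	78	27	24	33
mir-0026	43	40	20	22	21	21	24	34	20	45	36	40
mir-0027	99	182	128	158	107	116	86	55	153	145	63	77
mir-0028	78	111	29	60	98	70	110	49	70	110	58	124
mir-0029	3	25	4	15	31	9	9	11	27	12	12	20
mir-0030	68	27	56	16	66	37	42	58	98	44	34	48
mir-0031	9	11	17	10	2	8	11	11	6	14	9	19
mir-0032	634	985	1168	698	751	693	809	1795	1714	1191	1325	701
mir-0033	52	106	110	57	64	54	59	73	102	61	60	60
mir-0034	11	23	24	27	14	27	27	26	48	19	13	25
mir-0035	39	91	56	26	17	49	91	30	49	54	27	40
mir-0036	106	57	95	73	36	59	112	55	138	48	72	151
mir-0037	186	248	294	477	286	185	282	321	353	237	202	387
mir-0038	111	141	219	99	76	148	99	70	102	85	61	194
mir-0039	128	233	123	136	112	79	193	189	246	204	104	129
mir-0040	40	41	50	71	175	136	267	70	231	898	326	622
mir-0041	443	436	386	290	370	252	351	344	256	264	369	319
mir-0042	60	76	47	47	48	73	63	47	73	59	49	114
mir-0043	16	16	14	7	10	10	19	5	14	5	9	12
mir-0044	72	199	222	74	87	116	93	81	149	92	130	86
mir-0045	8	23	20	11	20	7	13	9	29	12	7	13
mir-0046	36	46	27	42	24	28	21	55	22	32	45	40
mir-0047	80	106	219	85	104	104	84	68	119	80	46	86
mir-0048	22	81	58	92	93	67	153	139	287	360	178	450
mir-0049	22	26	32	32	39	34	55	18	28	34	28	57
mir-0050	5	9	12	7	10	7	0	0	5	3	8	8
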