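116	117	44	52	85	92
62	163	84	56	278	79
27	21	79	18	62	28
17	36	39	64	28	26
606	632	994	643	461	594
50	64	114	41	57	78
1295	723	1045	375	932	252
135	337	271	469	353	428
156	139	80	232	26	208
33	75	129	61	24	67
63	85	60	80	86	89
44	149	98	228	36	75
28	67	24	27	30	44
98	82	87	118	194	103
77	103	33	41	49	32
157	189	125	115	171	182
170	25	92	117	132	85
693	783	707	442	332	681
118	37	100	86	12	99
99	120	84	75	61	186
42	36	49	89	24	86
215	100	171	37	322	106
83	31	141	95	76	116
267	211	266	215	204	131
98	128	76	287	127	127
126	179	90	168	196	283
127	116	58	210	80	60
50	35	48	55	30	32
79	142	84	98	62	190
57	37	54	89	57	33
47	48	18	47	24	65
47	47	70	60	55	56
296	220	255	243	124	231
28	31	41	30	33	24
81	67	57	91	54	62
310	171	206	113	82	326
171	125	126	193	160	37
1129	549	425	430	1024	1480
83	57	38	53	115	57
99	68	281	64	100	80
42	45	19	22	32	10
145	70	76	157	106	201
783	387	386	438	310	610
80	91	32	73	91	47
246	793	611	128	340	417
65	231	114	101	77	87
17	20	22	6	12	21
228	465	246	192	270	465
361	193	83	462	326	287
355	287	87	294	35	150
166	423	521	307	225	676
71	156	124	103	56	85
38	88	75	85	34	102
146	225	326	208	360	231
87	347	239	71	179	100
278	188	323	289	370	386
141	166	74	88	271	132
76	409	174	202	426	318
456	472	661	951	566	678
184	124	404	180	96	114
69	59	54	75	63	84
2057	932	1862	991	1122	1822
80	108	86	115	137	152
19	35	45	15	18	57
255	163	334	235	238	242
161	534	932	656	378	942
34	32	15	72	126	55
28	98	24	25	41	67
74	33	141	64	90	106
92	422	508	400	175	346
196	241	191	271	498	427
67	151	122	126	150	115
79	31	84	81	17	95
265	233	358	171	219	129
525	579	399	240	892	280
308	249	71	168	182	125
69	95	57	46	60	86
189	128	494	189	148	234
19	33	90	44	44	43
195	426	256	122	292	118
256	134	94	118	184	244
26	173	65	123	138	441
6	36	24	68	36	91
34	37	124	17	91	30
679	1929	3624	608	2485	1318
190	77	111	39	63	144
22	57	31	31	31	36
267	272	194	142	209	184
24	64	41	42	20	50
24	34	28	40	43	24
221	1552	553	586	585	608
50	47	73	42	85	78
244	316	305	443	205	247
29	75	59	172	35	90
70	245	88	291	142	239
105	94	151	70	61	61
702	418	907	362	1185	546
46	27	44	34	13	42
646	110	245	453	323	625
32	146	60	109	42	96
159	117	70	30	126	191
111	264	82	175	296	87
248	100	208	256	213	286
114	112	186	53	62	131
17	22	18	11	4	28
229	200	226	123	425	326
114	89	280	346	222	108
86	27	46	78	99	35
510	604	652	704	702	816
612	456	501	385	669	775
339	332	750	389	267	376
1251	540	585	281	1065	614
427	381	258	122	168	80
22	21	14	16	16	13
111	282	144	173	118	183
25	172	43	97	173	98
209	38	66	67	65	46
277	174	319	407	121	359
246	228	156	74	127	151
223	116	138	145	158	102
2355	2625	1036	1611	2208	837
72	74	76	136	163	108
431	1039	441	476	425	804
353	272	241	545	443	316
119	80	58	143	226	112
288	413	718	641	698	745
171	675	860	459	907	724
542	155	357	110	242	365
1189	955	650	359	807	1040
23	74	122	93	63	28
192	92	68	91	196	76
40	42	40	41	54	63
110	97	342	221	286	281
19	104	69	37	30	38
90	99	72	103	57	36
92	147	111	280	172	251
193	64	95	92	147	148
12	19	15	15	27	14
71	65	135	141	50	108
227	273	529	148	155	119
50	22	32	35	45	41
188	223	158	345	142	471
22	22	22	35	35	40
162	106	113	80	210	120
99	169	96	141	172	281
118	202	173	216	170	296
316	303	336	220	251	130
367	366	1549	1329	1548	568
138	93	60	186	84	102
319	289	168	134	149	219
26	16	20	35	28	24
313	260	250	396	395	584
194	358	242	163	278	211
566	267	294	236	205	178
94	61	79	76	84	53
274	158	283	286	307	647
887	619	483	1287	690	815
650	1178	212	245	827	536
142	22	56	59	83	78
144	186	125	161	77	106
109	173	106	198	94	324
96	84	124	117	57	68
244	280	300	140	273	233
192	71	145	229	227	227
23	33	48	59	71	42
53	100	172	89	48	25
55	55	45	60	47	44
106	109	124	53	72	75
265	144	219	94	140	69
137	188	136	54	89	94
312	104	86	214	276	257
159	289	168	370	150	179
381	281	443	237	255	259
111	251	228	179	177	357
70	67	61	56	146	59
356	416	734	431	598	185
61	58	27	28	72	52
627	278	686	530	515	247
499	223	395	529	195	364
419	334	373	219	426	477
70	179	104	116	132	80
147	215	60	214	138	301
353	261	285	248	330	335
73	65	63	32	67	60
1250	1362	1501	1526	1227	1337
155	97	172	177	217	48
166	105	150	81	113	74
280	186	257	63	106	163
37	76	178	60	72	32
128	132	216	148	278	190
57	135	292	187	57	43
84	150	90	127	91	94
599	465	311	483	251	234
112	167	114	174	143	116
321	399	116	218	101	150
2291	2577	1980	3098	3684	3016
1153	793	1253	1379	695	1140
28	34	32	24	34	39
155	460	148	202	68	278
160	558	493	413	267	238
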