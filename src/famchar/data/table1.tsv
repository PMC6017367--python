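name	locus_id	location	orf_bp	size_aa	domain_start	domain_end	pi	mw_kda	introns	full_length_bp
DlUBC1	Dlo_000106.1	scaffold1:985697:987091	567	188	32	174	7.08	21.65	4	1395
DlUBC2	Dlo_000292.1	scaffold1:3030633:3033521	483	160	8	158	8.42	18.00	4	2888
DlUBC3	Dlo_026265.1	scaffold6:2172282:2176388	459	152	7	150	5.37	17.35	4	4106
DlUBC4	Dlo_032644.1	scaffold9:121161:124354	519	172	29	172	6.82	18.74	3	3193
DlUBC5	Dlo_002066.1	scaffold11:28768:34251	447	148	4	147	7.72	16.49	3	5483
DlUBC6	Dlo_009607.1	scaffold19:759717:760407	330	109	1	107	6.50	12.75	2	691
DlUBC7	Dlo_011099.1	scaffold21:38074:42650	2769	922	676	833	4.77	102.86	6	4576
DlUBC8	Dlo_012344.1	scaffold23:232655:235481	528	175	1	139	4.18	19.99	5	2826
DlUBC9	Dlo_014547.1	scaffold27:1628072:1630343	462	153	8	152	4.83	17.48	3	2272
DlUBC10	Dlo_016672.1	scaffold32:473094:475341	537	178	1	139	4.16	20.08	5	2247
DlUBC11	Dlo_021485.1	scaffold45:1169893:1172427	486	161	18	161	7.00	18.43	5	2534
DlUBC12	Dlo_024241.1	scaffold54:747570:752709	3438	1145	894	1054	4.57	126.46	6	5139
DlUBC13	dlo_034965.1	scaffold54:903777:904902	447	148	4	147	7.68	16.51	3	1125
DlUBC14	Dlo_024956.1	scaffold56:49487:50629	1143	380	79	236	9.82	42.60	0	1142
DlUBC15	Dlo_024957.1	scaffold56:57967:58685	582	193	1	136	9.08	21.98	1	719
DlUBC16	Dlo_024978.1	scaffold56:225690:227300	915	304	14	174	5.89	34.00	4	1610
DlUBC17	Dlo_024979.1	scaffold56:228547:229700	540	179	14	155	6.59	20.69	3	1153
DlUBC18	Dlo_026358.1	scaffold60:843621:845935	447	148	4	147	7.69	16.39	3	2314
DlUBC19	Dlo_032160.2	scaffold87:1001138:1002555	612	203	61	203	5.50	22.39	6	1417
DlUBC20	Dlo_033394.1	scaffold94:238050:239736	330	109	1	107	5.50	12.44	3	1686
DlUBC21	Dlo_034066.1	scaffold99:423532:424482	267	88	1	86	8.82	9.90	4	950
DlUBC22	Dlo_001351.1	scaffold105:47204:51064	447	148	4	147	7.72	16.58	3	4250
DlUBC23	Dlo_005400.1	scaffold139:303181:306533	585	194	5	150	4.72	21.26	4	3352
DlUBC24	Dlo_009107.1	scaffold182:25126:28034	630	209	74	173	5.30	24.28	4	2908
DlUBC25	Dlo_009840.1	scaffold192:53161:56243	447	148	4	147	7.72	16.55	3	3082
DlUBC26	Dlo_009841.1	scaffold192:56889:58714	474	157	2	131	8.44	17.85	3	1825
DlUBC27	Dlo_010855.1	scaffold204:275311:285221	2088	695	332	489	4.79	77.60	7	9890
DlUBC28	Dlo_013399.1	scaffold247:138383:139816	447	148	4	147	7.72	16.46	3	1433
DlUBC29	Dlo_013592.1	scaffold250:137505:139550	552	183	32	174	8.61	21.01	4	2045
DlUBC30	Dlo_015182.2	scaffold286:460274:460720	447	148	29	142	8.55	17.22	0	446
DlUBC31	Dlo_016190.1	scaffold303:303486:307073	1617	538	258	415	5.99	59.98	6	3587
DlUBC32	Dlo_017847.1	scaffold347:238580:242477	735	244	1	132	9.60	26.47	4	3897
DlUBC33	Dlo_019295.1	scaffold388:24595:27323	1731	576	9	161	8.39	63.39	5	2728
DlUBC34	Dlo_021725.2	scaffold459:127808:133234	462	153	8	151	6.74	17.21	7	5426
DlUBC35	Dlo_031542.1	scaffold832:7085:11030	717	238	8	162	8.78	26.98	8	3945
DlUBC36	Dlo_032039.1	scaffold860:46363:48204	315	104	1	89	4.63	11.71	2	1841
DlUBC37	Dlo_001660.1	scaffold1077:94570:95523	954	317	68	228	6.08	37.35	0	953
DlUBC38	Dlo_006580.1	scaffold1489:71154:72782	483	160	8	158	8.39	18.06	4	1628
DlUBC39	Dlo_008135.1	scaffold1681:29423:31993	510	169	4	134	4.33	19.25	4	2570
DlUBC40	Dlo_008607.1	scaffold17588:7:484	243	80	2	68	4.12	9.04	2	478
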