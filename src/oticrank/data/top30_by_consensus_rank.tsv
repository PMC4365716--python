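probe_id	gene	ov_fold	ov_rank	hc_fold	hc_rank	sc_fold	sc_rank	consensus_group	consensus_score	consensus_rank
Fbxo2.c1	Fbxo2	14.62200927	2	233.462206	3	209.1084184	4	OV/HC/SC	9	1
Col9a2.c2	Col9a2	6.894714915	9	64.73931483	16	99.66541579	13	OV/HC/SC	38	2
Oc90.c3	Oc90	15.31678675	1	37.19151468	36	133.6813688	7	OV/HC/SC	44	3
Plekhb1.c4	Plekhb1	5.946512058	12	28.31080827	56	33.40807691	25	OV/HC/SC	93	4
S100a1.c5	S100a1	2.908877684	83	118.1935475	8	106.9791597	11	HC/SC	102	5
Gata3.c6	Gata3	7.034011368	8	17.05957342	99	22.63071352	39	OV/HC/SC	146	6
Fgf10.c7	Fgf10	4.700220155	24	13.8394988	125	17.82238697	64	OV/HC/SC	213	7
Fgf10.c8	Fgf10	4.314080209	37	13.59648272	128	16.99160918	71	OV/HC/SC	236	8
Btbd14a.c9	Btbd14a	2.583935277	107	12.9935202	138	24.78606653	34	HC/SC	279	9
Sh3gl2.c10	Sh3gl2	5.195890282	17	10.56169338	174	11.84953165	125	OV/HC/SC	316	10
Ap1m2.c11	Ap1m2	4.401733497	34	16.98844137	100	8.629079783	190	OV/HC/SC	324	11
Cldn3.c12	Cldn3	4.28578566	39	8.527481874	247	21.97050359	45	OV/HC/SC	331	12
Otolin.c13	Otolin	2.613673625	104	13.00452906	137	12.71711488	110	HC/SC	351	13
Faah.c14	Faah	3.024489321	75	9.804033123	197	12.65490027	111	HC/SC	383	14
Col2a1.c15	Col2a1	4.520159455	31	7.506419492	289	17.59092164	65	OV/HC/SC	385	15
Cd9.c16	Cd9	3.355323417	67	8.23098117	257	16.33853718	74	HC/SC	398	16
Col2a1.c17	Col2a1	4.232269996	40	7.827652714	271	14.83067647	89	OV/HC/SC	400	17
Kai1.c18	Kai1	1.755355331	295	19.26278326	88	20.30006957	55	HC/SC	438	18
Matn1.c19	Matn1	2.017228994	189	8.875465831	229	39.5214772	21	HC/SC	439	19
Gal3st1.c20	Gal3st1	2.881826605	86	10.55670683	175	8.735986943	186	HC/SC	447	20
Gjb2.c21	Gjb2	1.679839813	340	23.0501633	74	23.74169556	38	HC/SC	452	21
Ap1m2.c22	Ap1m2	3.920424836	52	13.46897818	132	6.465748986	291	HC/SC	475	22
Rab25.c23	Rab25	3.077388814	73	8.457112871	251	9.816023707	156	HC/SC	480	23
BC019731.c24	BC019731	2.606254615	105	24.07525961	68	6.247095999	308	HC/SC	481	24
Ush1c.c25	Ush1c	1.613973622	381	21.22888215	83	33.21939745	26	HC/SC	490	25
Ltbp3.c26	Ltbp3	1.657999303	354	14.0823195	122	35.97926226	23	HC/SC	499	26
Cyb561.c27	Cyb561	2.949823565	80	10.6399017	172	6.880909012	255	HC/SC	507	27
Gjb2.c28	Gjb2	1.521293061	452	38.97023609	32	35.09867751	24	HC/SC	508	28
Kcnk1.c29	Kcnk1	4.298354088	38	6.723838937	332	10.01882675	151	HC/SC	521	29
Faah.c30	Faah	2.569395243	109	8.469575034	250	9.13829701	168	HC/SC	527	30
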