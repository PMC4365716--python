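probe_id	gene	ov_mean	ov_sd	ov_fold	ov_q	ov_rank	ref_fold_abs	ref_upreg	hc_fold	hc_rank	sc_fold	sc_rank	consensus_group	consensus_score	consensus_rank
Oc90.1	Oc90	10.97366167	0.419246795	15.316797	2.08E-09	1	1.132771783	NS	37.191532	36	133.68132	7	OV/HC/SC	44	3
Fbxo2.2	Fbxo2	10.87404333	0.072690153	14.622012	1.74E-12	2	1.023630354	NS	233.46231	3	209.10844	4	OV/HC/SC	9	1
Lmx1a.3	Lmx1a	11.06934217	0.056113649	11.061509	3.38E-04	3	1.448138913	Periotic	1.071335	7460	2.1826358	1496	OV	8959	1220
Krt1-23.4	Krt1-23	10.25196333	0.288855995	10.184871	2.04E-09	4	1.220269579	NS	1.7182626	2426	7.448142	229	OV/SC	2659	259
Spp1.5	Spp1	9.971883833	0.332888479	8.454517	1.67E-10	5	1.136606365	NS	1.1694639	5352	1.0023074	16967	OV	22324	4802
Cldn6.6	Cldn6	13.18188567	0.089216859	7.5281053	3.69E-08	6	2.35525402	Embryo	1.8450933	2163	4.1609483	528	OV/SC	2697	264
Wfdc2.7	Wfdc2	13.53477267	0.213203	7.073592	5.33E-09	7	2.496286749	Embryo	3.2619166	904	14.833333	88	OV/SC	999	85
Gata3.8	Gata3	11.364921	0.142121662	7.0340185	1.49E-09	8	1.173139844	NS	17.05958	99	22.630722	39	OV/HC/SC	146	6
Col9a2.9	Col9a2	10.07369633	0.153509332	6.894713	1.49E-09	9	1.008878076	NS	64.73929	16	99.665436	13	OV/HC/SC	38	2
Arhgef19.10	Arhgef19	9.768474333	0.09629171	6.341925	2.08E-09	10	1.218514062	NS	4.2322383	639	14.127765	93	OV/HC/SC	742	49
Rbm35a.11	Rbm35a	12.29022383	0.143019237	6.3149257	6.10E-09	11	2.368308192	Embryo	2.1024952	1724	4.913607	432	OV/SC	2167	206
Plekhb1.12	Plekhb1	10.08439517	0.16829363	5.946511	6.30E-11	12	1.312607244	NS	28.310795	56	33.40806	25	OV/HC/SC	93	4
Hs3st1.13	Hs3st1	10.46399633	0.195136572	5.8575263	2.70E-09	13	1.048332013	NS	4.9308343	517	22.05582	44	OV/HC/SC	574	33
Rgcc.14	Rgcc	10.77107167	0.161833702	5.628432	1.19E-08	14	1.990202734	Embryo	4.3943467	600	9.030337	175	OV/HC/SC	789	56
Tbx2.15	Tbx2	9.984906	0.297733516	5.626228	9.24E-08	15	1.702381408	Embryo	4.6268463	553	3.1064396	849	OV/HC	1417	119
Prss8.16	Prss8	10.105778	0.16620698	5.5848174	1.45E-07	16	1.290586405	NS	5.4411964	442	12.075007	123	OV/HC/SC	581	35
Sh3gl2.17	Sh3gl2	9.860674833	0.135098031	5.195888	8.67E-11	17	1.002118118	NS	10.561689	174	11.849528	125	OV/HC/SC	316	10
Wfdc2.18	Wfdc2	9.499769333	0.302036446	5.1527414	2.46E-08	18	1.227582286	NS	2.319336	1489	9.602433	161	OV/SC	1668	148
Marveld3.19	Marveld3	9.041756667	0.133118972	5.006034	3.82E-09	19	1.094974091	NS	5.016969	502	9.084135	171	OV/HC/SC	692	45
Vwa2.20	Vwa2	9.691604	0.165306445	4.864665	5.78E-08	20	1.376504348	NS	1.0021158	10270	5.5677967	364	OV/SC	10654	1500
Bdnf.21	Bdnf	9.836624667	0.178453967	4.78742	8.09E-09	21	1.246577778	NS	9.485823	208	1.0017089	19301	OV/HC	19530	3740
Espn.22	Espn	10.76721233	0.250324449	4.7623343	1.19E-08	22	2.301431921	Embryo	21.954702	79	1.1772411	5296	OV/HC	5397	653
Plekha4.23	Plekha4	9.914148	0.299348822	4.7167573	8.07E-09	23	1.282688658	NS	4.1990533	647	6.789616	262	OV/HC/SC	932	75
Fgf10.24	Fgf10	10.70834767	0.021669661	4.700219	2.49E-09	24	2.193222734	Embryo	13.839492	125	17.822388	64	OV/HC/SC	213	7
Car4.25	Car4	10.77693067	0.369327027	4.63751	2.23E-06	25	1.171838835	NS	3.679346	25122	3.4888153	24946	OV	50093	18760
Prr15.26	Prr15	9.310321667	0.225649081	4.6330085	2.20E-08	26	1.146866527	NS	6.245964	378	7.0138445	249	OV/HC/SC	653	42
Col6a1.27	Col6a1	10.12810567	0.204186116	4.622068	2.27E-09	27	1.199047241	NS	1.2619317	21404	1.151628	5720	OV	27151	7232
Six1.28	Six1	11.91456133	0.035842889	4.5915775	2.49E-09	28	1.492275252	Embryo	5.8167586	403	5.891639	328	OV/HC/SC	759	52
Socs2.29	Socs2	12.39277283	0.234257353	4.547705	2.49E-09	29	1.097722074	NS	5.1087866	493	5.8204165	339	OV/HC/SC	861	64
Myo7a.30	Myo7a	9.023172167	0.481244122	4.538013	1.31E-07	30	1.027957463	NS	28.857481	55	1.0124729	11440	OV/HC	11525	1651
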