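family	compartment	tissue	n	co_n	co_pct	counter_n	counter_pct	mc_p
L1	gene	cerebellum	842	345	40.97	497	59.03	<0.001
L1	gene	frontal_cortex	236	97	41.10	139	58.90	0.02
L1	gene	SVZ	584	239	40.92	345	59.08	0.001
L1	gene	DG	1558	644	41.34	914	58.66	<0.001
L1	gene	myocardium	578	234	40.48	344	59.52	0.01
L1	promoter	cerebellum	92	38	41.30	54	58.70	0.004
L1	promoter	frontal_cortex	31	20	64.52	11	35.48	0.002
L1	promoter	SVZ	74	31	41.89	43	58.11	0.002
L1	promoter	DG	177	88	49.72	89	50.28	<0.001
L1	promoter	myocardium	62	34	54.84	28	45.16	0.032
Alu	gene	cerebellum	623	323	51.85	301	48.15	NS
Alu	gene	frontal_cortex	1028	497	48.35	531	51.65	NS
Alu	gene	SVZ	609	304	49.92	305	50.08	NS
Alu	gene	DG	1465	691	47.17	774	52.83	0.013
Alu	gene	myocardium	589	279	47.37	310	52.63	NS
Alu	promoter	cerebellum	67	29	43.28	38	56.72	NS
Alu	promoter	frontal_cortex	105	43	40.95	62	59.05	NS
Alu	promoter	SVZ	61	32	52.46	29	47.54	NS
Alu	promoter	DG	105	45	42.86	60	57.14	0.021
Alu	promoter	myocardium	55	25	45.45	30	54.55	NS
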