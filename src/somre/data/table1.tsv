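family	tissue	total_reads	somatic_reads	somatic_insertions	rate_pct	genic_n	genic_pct	promoter_n	promoter_pct
L1	cerebellum	2723127	1712	1651	0.0629	842	51.00	92	5.57
L1	frontal_cortex	825363	475	462	0.0576	236	51.08	31	6.71
L1	SVZ	1845367	1161	1133	0.0629	584	51.54	74	6.53
L1	DG	3435529	3211	3100	0.0935	1558	50.26	177	5.71
L1	myocardium	1880295	1170	1151	0.0622	578	50.22	62	5.39
Alu	cerebellum	11978540	1376	1317	0.0115	623	47.30	67	5.09
Alu	frontal_cortex	11962901	2217	2138	0.0185	1028	48.08	105	4.91
Alu	SVZ	10921385	1353	1308	0.0124	609	46.56	61	4.66
Alu	DG	13339041	3079	2984	0.0231	1465	49.10	105	3.52
Alu	myocardium	13011266	1275	1243	0.0098	589	47.39	55	4.42
combined	cerebellum	NA	NA	NA	NA	NA	49.36	NA	5.36
combined	frontal_cortex	NA	NA	NA	NA	NA	48.62	NA	5.23
combined	SVZ	NA	NA	NA	NA	NA	48.87	NA	5.53
combined	DG	NA	NA	NA	NA	NA	49.69	NA	4.64
combined	myocardium	NA	NA	NA	NA	NA	48.75	NA	4.89
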