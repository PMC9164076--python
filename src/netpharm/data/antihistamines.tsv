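name	mw	hba	hbd	mlogp	violations	ba_score	tpsa
Diphenhydramine	255.35	2	0	3.16	0	0.55	12.47
Clemastine	343.89	2	0	4.18	1	0.55	12.47
Triprolidine	278.39	2	0	3.16	0	0.55	16.13
Hydroxyzine	374.9	4	1	2.45	0	0.55	35.94
Cypropheptadine	287.4	1	0	4.46	1	0.55	3.24
Promethazine	284.42	1	0	3.84	0	0.55	31.78
Antazoline	265.35	1	1	2.89	0	0.55	27.63
Dimetindene	292.42	2	0	3.39	0	0.55	16.13
Ketotifen	309.43	2	0	3.12	0	0.55	48.55
Terfenadine	471.67	3	2	4.80	1	0.55	43.70
Loratadine	382.88	3	0	3.72	0	0.55	42.43
Ebastine	469.66	3	0	4.73	1	0.55	29.54
Cetirizine	388.89	5	1	2.35	0	0.55	53.01
Rupatadine	415.96	3	0	4.03	0	0.55	29.02
Mizolastine	432.49	4	1	3.59	0	0.55	70.05
Emedastine	302.41	3	0	1.91	0	0.55	33.53
Azelastine	381.9	3	0	4.28	1	0.55	38.13
Bilastine	463.61	5	1	3.29	0	0.55	67.59
Desloratadine	310.82	2	1	3.66	0	0.55	24.92
Fexofenadine	501.66	5	3	3.86	1	0.55	81.00
Levocetirizine	388.89	5	1	2.35	0	0.55	53.01
Buclizine	433.03	2	0	5.38	1	0.55	6.48
Trimeprazine	298.45	1	0	4.08	0	0.55	31.78
Carbinoxamine	290.79	3	0	2.16	0	0.55	25.36
Tripelenamine	255.36	2	0	2.32	0	0.55	19.37
Meclizine	390.95	2	0	4.78	1	0.55	6.48
Methdilazine	296.43	1	0	4.08	0	0.55	31.78
Dexchlorpheniramine	274.79	2	0	3.04	0	0.55	16.13
Dimenhydrinate	469.96	5	1	2.30	0	0.55	85.15
Brompheniramine	319.24	2	0	3.16	0	0.55	16.13
Chlorpheniramine	274.79	2	0	3.04	0	0.55	16.13
Cyclizine	266.38	2	0	3.01	0	0.55	6.48
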