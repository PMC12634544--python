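variable	unit	B1_mean	B1_sd	B2_mean	B2_sd	B3_mean	B3_sd	B4_mean	B4_sd
pH	-	7.68	0.13	8.05	0.08	7.62	0.15	7.72	0.06
EC	uS/cm	131.33	3.27	82.00	4.58	135.00	10.25	128.00	6.08
SOC	%	1.16	0.06	1.11	0.07	1.40	0.06	1.39	0.08
TN	%	0.13	0.01	0.13	0.01	0.16	0.01	0.16	0.01
AP	mg/kg	60.34	3.23	63.42	1.49	89.41	5.15	111.16	2.67
AK	mg/kg	390.52	9.83	450.91	6.23	486.55	35.46	372.41	27.96
BG	umol/d/g	62.74	4.72	51.90	4.01	44.87	3.38	52.58	0.57
NAG	umol/d/g	20.94	1.18	21.96	1.34	25.45	0.89	21.06	0.31
LAP	umol/d/g	10.50	0.51	14.92	0.21	29.37	0.78	21.33	0.89
ALP	umol/d/g	5.91	0.33	8.63	0.36	6.95	0.45	6.75	0.10
PPO	umol/d/g	32.17	2.06	36.35	2.07	53.98	2.03	44.56	1.95
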