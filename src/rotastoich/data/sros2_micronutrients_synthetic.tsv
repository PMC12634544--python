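variable	unit	B1_mean	B1_sd	B2_mean	B2_sd	B3_mean	B3_sd	B4_mean	B4_sd
Fe	mg/kg	28000	900	27800	900	28500	950	28300	900
Mg	mg/kg	5200	170	5150	160	5300	175	5260	170
Ca	mg/kg	3100	110	3000	105	3780	130	3720	125
Mn	mg/kg	480	25	430	22	700	34	878	40
S	mg/kg	310	11	295	10	330	12	350	12
Zn	mg/kg	85	3.0	80	2.8	90	3.2	95.2	3.4
Cu	mg/kg	28	1.0	25	0.9	27	1.0	27.5	1.0
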