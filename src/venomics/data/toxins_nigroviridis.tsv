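transcript_id	orthology_label	family	tpm_CLP1856	tpm_CLP1864	over_expression	presence_CLP1856	presence_CLP1864
Bnigro-BPP-1	Ortholog	BPP	29752.98	52897.54	CLP1864	+	+
Bnigro-CTL-1	Ortholog	CTL	5601.97	3.99	CLP1856	+	-
Bnigro-CTL-2	Ortholog	CTL	47.42	4353.63	CLP1864	-	+
Bnigro-CTL-3	Ortholog	CTL	4669.5	3027.69	-	+	+
Bnigro-CTL-4	Paralog	CTL	5395.92	4095.4	-	+	+
Bnigro-CTL-5	Paralog	CTL	7653.39	26592.73	CLP1864	+	+
Bnigro-CTL-6	Paralog	CTL	8809.55	3537.01	-	+	+
Bnigro-CTL-7	Paralog	CTL	0	22739.95	CLP1864	-	+
Bnigro-HYAL-1	Ortholog	HYAL	196.31	76.03	-	+	+
Bnigro-LAAO-1	Ortholog	LAAO	2070.21	412.19	CLP1856	+	+
Bnigro-NGF-1	Ortholog	NGF	836.47	1692.1	-	+	+
Bnigro-NUC-1	Ortholog	NUC	1575.76	1532.59	-	+	+
Bnigro-PDE-1	Ortholog	PDE	1356.81	524.9	-	+	+
Bnigro-PLA2-1	Ortholog	PLA2	53023.62	183732.85	CLP1864	+	+
Bnigro-PLA2-2	Ortholog	PLA2	102035.05	235935.29	CLP1864	+	+
Bnigro-SVMPII-1	Ortholog	SVMPII	3405.08	327.07	CLP1856	+	-
Bnigro-SVMPII-2	Ortholog	SVMPII	4055.07	290.21	CLP1856	+	-
Bnigro-SVMPII-3	Ortholog	SVMPII	3980.17	24.59	CLP1856	+	-
Bnigro-SVMPII-4	Paralog	SVMPII	52404.14	11942.88	-	+	+
Bnigro-SVMPIII-1	Ortholog	SVMPIII	0.68	73.09	CLP1864	-	+
Bnigro-SVMPIII-2	Ortholog	SVMPIII	2157.48	151.17	CLP1856	+	+
Bnigro-SVMPIII-3	Ortholog	SVMPIII	12908.06	124.4	CLP1856	+	+
Bnigro-SVMPIII-4	Ortholog	SVMPIII	6587.36	2375.96	CLP1856	+	-
Bnigro-SVMPIII-5	Ortholog	SVMPIII	48324.54	19456.86	-	+	+
Bnigro-SVSP-1	Ortholog	SVSP	5067.97	24092.29	CLP1864	+	+
Bnigro-SVSP-2	Ortholog	SVSP	4588.27	3441.02	-	+	+
Bnigro-SVSP-3	Ortholog	SVSP	1633.58	4877.37	CLP1864	+	+
Bnigro-SVSP-4	Ortholog	SVSP	1174.85	19016.69	CLP1864	+	+
Bnigro-SVSP-5	Ortholog	SVSP	552.15	644.59	-	+	+
Bnigro-SVSP-6	Ortholog	SVSP	1712.44	8567.09	CLP1864	-	+
Bnigro-SVSP-7	Ortholog	SVSP	792.67	4112.06	CLP1864	+	+
Bnigro-SVSP-8	Ortholog	SVSP	17931.94	0.41	CLP1856	+	-
Bnigro-SVSP-9	Paralog	SVSP	11.35	25032.15	CLP1864	-	+
Bnigro-SVSP-10	Paralog	SVSP	183.43	2875.45	CLP1864	+	+
Bnigro-SVSP-11	Paralog	SVSP	2827.4	0.16	CLP1856	+	-
Bnigro-SVSP-12	Paralog	SVSP	3.89	8988.68	CLP1864	-	+
Bnigro-SVSP-13	Paralog	SVSP	21317.45	0	CLP1856	+	-
Bnigro-VEGF-1	Ortholog	VEGF	56.56	17963.5	CLP1864	+	+
Bnigro-VEGF-2	Ortholog	VEGF	33.93	117.99	-	+	+
Bnigro-VEGF-3	Ortholog	VEGF	14.81	62.5	-	+	+
Bnigro-VEGF-4	Ortholog	VEGF	25.22	77.81	-	+	+
Bnigro-Vespryn-1	Paralog	Vespryn	8.98	45.01	-	+	+
Bnigro-Waprin-1	Ortholog	Waprin	24.92	36.31	-	+	+
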