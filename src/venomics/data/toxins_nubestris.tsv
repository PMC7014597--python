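transcript_id	orthology_label	family	tpm_CLP1859	tpm_CLP1865	over_expression	presence_CLP1859	presence_CLP1865
Bnubes-BPP-1	Ortholog	BPP	5097.77	63484.01	CLP1865	-	+
Bnubes-CRISP-1	Paralog	CRISP	17682.06	8634.01	CLP1859	+	+
Bnubes-CTL-1	Ortholog	CTL	48790.44	5771.89	-	+	+
Bnubes-CTL-2	Ortholog	CTL	13469.89	9134.83	-	+	+
Bnubes-CTL-3	Ortholog	CTL	18273.91	8462.73	CLP1859	+	+
Bnubes-CTL-4	Paralog	CTL	134247.25	46096.08	CLP1859	+	+
Bnubes-CTL-5	Paralog	CTL	93992.03	44194.92	CLP1859	+	+
Bnubes-CTL-6	Paralog	CTL	41975.12	3098.03	CLP1859	+	+
Bnubes-HYAL-1	Ortholog	HYAL	312.56	480.7	-	+	+
Bnubes-KUN-1	Paralog	KUN	211.54	231.29	-	+	+
Bnubes-LAAO-1	Ortholog	LAAO	6946.11	12529.4	-	+	+
Bnubes-NGF-1	Ortholog	NGF	3347.21	5435.31	-	+	+
Bnubes-NUC-1	Ortholog	NUC	1184.42	2318.22	-	+	+
Bnubes-PDE-1	Ortholog	PDE	1156.15	1461.55	-	+	+
Bnubes-PLA2-1	Ortholog	PLA2	3073.31	3700.01	-	+	+
Bnubes-PLA2-2	Ortholog	PLA2	2321.73	209.08	CLP1859	+	+
Bnubes-PLA2-3	Paralog	PLA2	4646.19	1726.32	CLP1865	+	+
Bnubes-SVMPII-1	Ortholog	SVMPII	11115.83	7867.18	-	+	+
Bnubes-SVMPII-2	Ortholog	SVMPII	7446.39	7182.3	-	+	+
Bnubes-SVMPII-3	Ortholog	SVMPII	85.26	6966.13	CLP1865	+	+
Bnubes-SVMPII-4	Paralog	SVMPII	9408.28	9519.11	-	+	+
Bnubes-SVMPII-5	Paralog	SVMPII	72976.35	2932.86	-	+	+
Bnubes-SVMPIII-1	Ortholog	SVMPIII	4.02	52.08	CLP1865	-	+
Bnubes-SVMPIII-2	Ortholog	SVMPIII	7436.41	6075.36	-	+	+
Bnubes-SVMPIII-3	Ortholog	SVMPIII	14334.66	14644.25	-	+	+
Bnubes-SVMPIII-4	Ortholog	SVMPIII	6744.23	10192.23	-	+	+
Bnubes-SVMPIII-5	Ortholog	SVMPIII	131295.22	69281.92	CLP1859	+	+
Bnubes-SVMPIII-6	Paralog	SVMPIII	808.43	2990.11	-	+	+
Bnubes-SVSP-1	Ortholog	SVSP	5793.23	2477.48	CLP1859	+	+
Bnubes-SVSP-2	Ortholog	SVSP	1544.31	2924.28	-	+	+
Bnubes-SVSP-3	Ortholog	SVSP	3126.56	3125.05	-	+	+
Bnubes-SVSP-4	Ortholog	SVSP	7665.15	2252.2	CLP1859	+	+
Bnubes-SVSP-5	Ortholog	SVSP	2301.11	4094.43	-	+	+
Bnubes-SVSP-6	Ortholog	SVSP	5123.44	2684.33	-	+	+
Bnubes-SVSP-7	Ortholog	SVSP	795.14	393.28	-	+	+
Bnubes-SVSP-8	Ortholog	SVSP	3207.97	10487.13	-	+	+
Bnubes-SVSP-9	Paralog	SVSP	823.13	475.48	-	+	+
Bnubes-VEGF-1	Ortholog	VEGF	3542.02	413.99	CLP1859	+	+
Bnubes-VEGF-2	Ortholog	VEGF	222.72	119.16	-	+	+
Bnubes-VEGF-3	Ortholog	VEGF	109.03	51.22	-	+	+
Bnubes-VEGF-4	Ortholog	VEGF	61.69	68.27	-	+	+
Bnubes-Waprin-1	Ortholog	Waprin	28.73	25.35	-	+	+
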