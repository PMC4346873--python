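# reconstruction: edge wiring satisfies printed degree constraints; unpublished wiring filled deterministically
compound_id	target_id	source	svm	rf	dock
M_01	COX2	predicted	0.8	0.7	40.5
M_01	PPARD	predicted	0.87	0.81	41.8
M_02	STAT1	predicted	0.94	0.92	43.1
M_04	ALOX5	predicted	0.81	0.78	44.4
M_04	CHUK	predicted	0.88	0.89	45.7
M_04	COX2	predicted	0.95	0.75	47.0
M_04	CYP1A2	predicted	0.82	0.86	48.3
M_04	EGFR	predicted	0.89	0.72	49.6
M_04	GSK3B	predicted	0.96	0.83	50.9
M_04	HMOX1	predicted	0.83	0.94	52.2
M_04	ICAM1	predicted	0.9	0.8	53.5
M_04	IKBKB	predicted	0.97	0.91	54.8
M_04	IL1A	predicted	0.84	0.77	56.1
M_04	PPARG	predicted	0.91	0.88	57.4
M_04	RELA	predicted	0.98	0.74	58.7
M_04	SELE	predicted	0.85	0.85	60.0
M_04	TNF	literature	0.92	0.71	61.3
M_05	AKR1B1	predicted	0.99	0.82	62.6
M_05	ALOX15	predicted	0.86	0.93	63.9
M_05	ALOX5	predicted	0.93	0.79	65.2
M_05	BCHE	predicted	0.8	0.9	66.5
M_05	BIRC5	predicted	0.87	0.76	67.8
M_05	CCL2	predicted	0.94	0.87	69.1
M_05	CD40LG	predicted	0.81	0.73	70.4
M_05	CDK2	predicted	0.88	0.84	41.7
M_05	CHRM1	predicted	0.95	0.7	43.0
M_05	CHUK	predicted	0.82	0.81	44.3
M_05	COX1	literature	0.89	0.92	45.6
M_05	COX2	literature	0.96	0.78	46.9
M_05	CXCL10	predicted	0.83	0.89	48.2
M_05	CXCL2	predicted	0.9	0.75	49.5
M_05	CYP1A2	predicted	0.97	0.86	50.8
M_05	EGFR	predicted	0.84	0.72	52.1
M_05	GSK3B	predicted	0.91	0.83	53.4
M_05	HMGCR	predicted	0.98	0.94	54.7
M_05	HMOX1	predicted	0.85	0.8	56.0
M_05	ICAM1	predicted	0.92	0.91	57.3
M_05	IKBKB	predicted	0.99	0.77	58.6
M_05	IL10	predicted	0.86	0.88	59.9
M_05	IL1A	predicted	0.93	0.74	61.2
M_05	IL1B	predicted	0.8	0.85	62.5
M_05	IL2	predicted	0.87	0.71	63.8
M_05	IL6	predicted	0.94	0.82	65.1
M_05	IL8	predicted	0.81	0.93	66.4
M_05	MAPK14	predicted	0.88	0.79	67.7
M_05	MAPK8	predicted	0.95	0.9	69.0
M_05	NFKBIA	predicted	0.82	0.76	70.3
M_05	NOS3	predicted	0.89	0.87	41.6
M_05	ODC1	predicted	0.96	0.73	42.9
M_05	PPARA	predicted	0.83	0.84	44.2
M_05	PPARG	predicted	0.9	0.7	45.5
M_05	RELA	predicted	0.97	0.81	46.8
M_05	SELE	predicted	0.84	0.92	48.1
M_05	SPP1	predicted	0.91	0.78	49.4
M_05	TNF	predicted	0.98	0.89	50.7
M_06	JUN	predicted	0.85	0.75	52.0
M_07	PLA2G1B	predicted	0.92	0.86	53.3
M_07	PPARG	predicted	0.99	0.72	54.6
M_12	RELA	predicted	0.86	0.83	55.9
M_13	TNF	predicted	0.93	0.94	57.2
M_14	AKR1B1	predicted	0.8	0.8	58.5
M_14	ALOX15	predicted	0.87	0.91	59.8
M_14	ALOX5	literature	0.94	0.77	61.1
M_14	BCHE	predicted	0.81	0.88	62.4
M_14	BIRC5	predicted	0.88	0.74	63.7
M_14	CCL2	predicted	0.95	0.85	65.0
M_14	CD40LG	predicted	0.82	0.71	66.3
M_14	CDK2	predicted	0.89	0.82	67.6
M_14	COX2	predicted	0.96	0.93	68.9
M_14	CXCL10	predicted	0.83	0.79	70.2
M_14	CXCL2	predicted	0.9	0.9	41.5
M_14	HMGCR	predicted	0.97	0.76	42.8
M_14	PPARG	predicted	0.84	0.87	44.1
M_14	RELA	predicted	0.91	0.73	45.4
M_14	TNF	predicted	0.98	0.84	46.7
M_28	COX2	predicted	0.85	0.7	48.0
M_28	PARP1	predicted	0.92	0.81	49.3
M_29	ALOX5	predicted	0.99	0.92	50.6
M_29	COX1	predicted	0.86	0.78	51.9
M_29	COX2	literature	0.93	0.89	53.2
M_29	IL10	predicted	0.8	0.75	54.5
M_29	IL1B	predicted	0.87	0.86	55.8
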