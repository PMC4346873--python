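target_id	protein_name	gene	uniprot	shared_with_drugs
P_01	3-hydroxy-3-methylglutaryl-Coenzyme A reductase	HMGCR	P04035	0
P_02	Aldose reductase	AKR1B1	P15121	0
P_03	Arachidonate 15-lipoxygenase	ALOX15	P16050	0
P_04	Arachidonate 5-lipoxygenase	ALOX5	P09917	1
P_05	Baculoviral IAP repeat-containing protein 5	BIRC5	O15392	0
P_06	C-C motif chemokine 2	CCL2	P13500	0
P_07	CD40 ligand	CD40LG	P29965	0
P_08	Cell division protein kinase 2	CDK2	P24941	0
P_09	Cholinesterase	BCHE	P06276	0
P_10	C-X-C motif chemokine 10	CXCL10	P02778	0
P_11	C-X-C motif chemokine 2	CXCL2	P19875	0
P_12	Cytochrome P450 1A2	CYP1A2	P05177	0
P_13	Epidermal growth factor receptor	EGFR	P00533	0
P_14	E-selectin	SELE	P16581	0
P_15	Glycogen synthase kinase-3 beta	GSK3B	P49841	0
P_16	Heme oxygenase 1	HMOX1	P09601	0
P_17	Inhibitor of nuclear factor kappa-B kinase subunit alpha	CHUK	O15111	0
P_18	Inhibitor of nuclear factor kappa-B kinase subunit beta	IKBKB	O14920	0
P_19	Intercellular adhesion molecule 1	ICAM1	P05362	1
P_20	Interleukin-1 alpha	IL1A	P01583	0
P_21	Interleukin-1 beta	IL1B	P01584	0
P_22	Interleukin-10	IL10	P22301	0
P_23	Interleukin-2	IL2	P60568	0
P_24	Interleukin-6	IL6	P05231	0
P_25	Interleukin-8	IL8	P10145	0
P_26	Mitogen-activated protein kinase 14	MAPK14	Q16539	0
P_27	Mitogen-activated protein kinase 8	MAPK8	P45983	0
P_28	Muscarinic acetylcholine receptor M1	CHRM1	P11229	0
P_29	NF-kappa-B inhibitor alpha	NFKBIA	P25963	0
P_30	Nitric-oxide synthase, endothelial	NOS3	P29474	0
P_31	Ornithine decarboxylase	ODC1	P11926	0
P_32	Osteopontin	SPP1	P10451	0
P_33	Peroxisome proliferator-activated receptor alpha	PPARA	Q07869	0
P_34	Peroxisome proliferator-activated receptor delta	PPARD	Q03181	1
P_35	Peroxisome proliferator-activated receptor gamma	PPARG	P37231	1
P_36	Phospholipase A2	PLA2G1B	Q9BS22	0
P_37	Poly [ADP-ribose] polymerase 1	PARP1	P09874	0
P_38	Prostaglandin G/H synthase 1	COX1	P23219	1
P_39	Prostaglandin G/H synthase 2	COX2	P35354	1
P_40	Signal transducer and activator of transcription 1-alpha/beta	STAT1	P42224	0
P_41	Transcription factor AP-1	JUN	P05412	0
P_42	Transcription factor p65	RELA	Q96F54	0
P_43	Tumor necrosis factor	TNF	P01375	0
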