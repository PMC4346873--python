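compound_id	name	ob	caco2	dl	content	bioactivities
M_01	β-sitosterol	45.04	1.33	0.75		anti-inflammation (6967611); antipyretic (6967611); anthelminthic & anti-mutagenic activities (12203259); anti-oxidative (16508147)
M_02	tormentic acid	33.73	-0.20	0.71		anti-inflammation (12007601); anti-HIV (12907261); antidiabetic (11830140); antitumor-promoting (14745168)
M_03	sanguisorba,officinalis-7	35.32	-0.25	0.71
M_04	rutin	35.45	-1.91	0.28		anti-inflammation (11680812); antioxidant (10904145)
M_05	quercetin	31.36	0.02	0.28		antioxidant (9414116); anti-inflammation (18549926); pro-apoptotic (14688022)
M_06	pomolic acid	75.45	0.26	0.73		anti-inflammation (18260049); anticancer (22223345); anti-apoptotic (15694664); anti-HIV (9748372)
M_07	oleanolic acid	66.91	0.61	0.76		anti-inflammation (1359067); antioxidant (22891614); anti-HIV (9748372); antidiabetic (18066109); hepatoprotection (18066109); antibacterial (18069238)
M_08	methyl ursolate	47.63	0.92	0.74		anti-inflammation (16204964)
M_09	methyl maslinate	42.79	0.32	0.72
M_10	methyl betulinate	43.41	0.85	0.76
M_11	methyl arjunolate	56.25	-0.05	0.70		anti-inflammation (16204964)
M_12	maslinic acid	55.84	0.04	0.74		anti-inflammation (3769076); anti-HIV (8759159); antioxidant (12802735); anti-tumor (20509140); antiangiogenic (21175131)
M_13	linguersinol	48.60	-0.17	0.54
M_14	kaempferol	65.70	0.27	0.24		anti-inflammation (17666881); analgesic (17666881); antioxidant (17551714); anti-bacteria (15234754)
M_15	delta 7-stigmastenol	40.40	1.30	0.75
M_16	2α-hydroxy ursolic acid	39.30	0.03	0.74		anti-cancer (15922841)
M_17	arjunolic acid	43.27	-0.27	0.72		antioxidant (18273903)
M_18	3-O-trans-p-coumaroyltormentic acid	46.94	-0.17	0.34		anti-inflammation (16204964)
M_19	3-O-trans-caffeoyltormentic acid	36.33	-0.07	0.32
M_20	3-O-cis-p-coumaroyltormentic acid	33.35	-0.19	0.34		anti-inflammation (16204964)
M_21	3-epiursolic acid	39.92	0.51	0.75
M_22	2α,3α-dihydroxyursolic acid	37.73	0.25	0.74
M_23	2α,3α-dihydroxyurs-12-en-28-oic acid	45.16	0.21	0.74
M_24	2α,3α,23-trihydroxyolean-12-en-28-oic acid	41.34	-0.27	0.72		anti-inflammation (16204964)
M_25	2α,3α,19α-trihydroxy-12-oleanen-28-oic acid	30.03	-0.18	0.72
M_26	2α,19α-dihydroxy-3-oxo-urs-12-en-28-oic acid	46.95	-0.30	0.71		anti-HIV (12907261)
M_27	ursolic acid	9.95	0.79	0.66	7.57	anti-inflammation (19051345); anti-HIV (8759159); hepatoprotection (8847885); antiangiogenic (21175131); anti-cancer (15922841); antibacterial (18069238)
M_28	chlorogenic acid	63.12	-1.07	0.33		antioxidant (12771329); anticarcinogenic (12771329); anti-inflammation (17077520); analgesic (17077520)
M_29	caffeic acid	51.08	0.24	0.05		antioxidant (16243424); anticoagulant (19678956); anti-inflammation (19678956)
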