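# reconstruction: FDA drug-target wiring; printed constraints (176 edges, NR3C1=32, COX2=28, COX1=24) satisfied, remainder deterministic
drug_id	target_id
D_01	COX1
D_01	COX2
D_01	NR3C1
D_02	COX1
D_02	COX2
D_02	NR3C1
D_03	COX1
D_03	COX2
D_03	NR3C1
D_04	COX1
D_04	COX2
D_04	NR3C1
D_05	COX1
D_05	COX2
D_05	NR3C1
D_06	COX1
D_06	COX2
D_06	NR3C1
D_07	COX1
D_07	COX2
D_07	NR3C1
D_08	COX1
D_08	COX2
D_08	NR3C1
D_09	COX1
D_09	COX2
D_09	NR3C1
D_10	COX1
D_10	COX2
D_10	NR3C1
D_11	COX1
D_11	COX2
D_11	NR3C1
D_12	COX1
D_12	COX2
D_12	NR3C1
D_13	COX1
D_13	COX2
D_13	NR3C1
D_14	COX1
D_14	COX2
D_14	NR3C1
D_15	COX1
D_15	COX2
D_15	NR3C1
D_16	COX1
D_16	COX2
D_16	NR3C1
D_17	COX1
D_17	COX2
D_17	NR3C1
D_18	COX1
D_18	COX2
D_18	NR3C1
D_19	COX1
D_19	COX2
D_19	NR3C1
D_20	COX1
D_20	COX2
D_20	NR3C1
D_21	COX1
D_21	COX2
D_21	NR3C1
D_22	COX1
D_22	COX2
D_22	NR3C1
D_23	ALOX5
D_23	COX2
D_23	NR3C1
D_24	COX2
D_24	NR3C1
D_24	PPARG
D_25	COX2
D_25	ICAM1
D_25	NR3C1
D_26	COX1
D_26	COX2
D_26	NR3C1
D_27	COX2
D_27	NR3C1
D_27	PPARD
D_28	G_01
D_28	G_02
D_28	NR3C1
D_29	G_03
D_29	G_04
D_29	NR3C1
D_30	G_05
D_30	G_06
D_30	NR3C1
D_31	G_07
D_31	G_08
D_31	NR3C1
D_32	G_09
D_32	G_10
D_32	G_11
D_33	G_12
D_33	G_13
D_33	G_14
D_34	G_15
D_34	G_16
D_34	G_17
D_35	G_18
D_35	G_19
D_35	NR3C1
D_36	ALOX5
D_36	COX2
D_36	PPARG
D_37	COX1
D_37	ICAM1
D_37	PPARD
D_38	G_01
D_38	G_02
D_38	G_03
D_39	G_04
D_39	G_05
D_39	G_06
D_40	G_07
D_40	G_08
D_40	G_09
D_41	G_10
D_41	G_11
D_42	G_12
D_42	G_13
D_43	G_14
D_43	G_15
D_44	G_16
D_44	G_17
D_45	G_18
D_45	G_19
D_46	G_20
D_46	G_21
D_47	G_22
D_47	G_23
D_48	G_24
D_48	G_25
D_49	G_26
D_49	G_27
D_50	G_28
D_50	G_29
D_51	G_30
D_51	G_31
D_52	G_32
D_52	G_33
D_53	G_34
D_53	G_35
D_54	G_36
D_54	G_37
D_55	G_38
D_55	G_39
D_56	G_40
D_56	G_41
D_57	G_42
D_57	G_43
D_58	G_44
D_58	G_45
D_59	G_46
D_60	G_47
D_61	G_48
D_62	G_49
D_63	G_50
D_64	G_51
D_65	G_52
D_66	G_53
D_67	G_54
D_68	G_55
D_69	G_56
D_70	G_57
D_71	G_58
D_72	G_59
D_73	G_60
D_74	G_61
D_75	G_62
D_76	G_63
D_77	G_64
D_78	G_65
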