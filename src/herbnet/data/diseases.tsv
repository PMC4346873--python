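# reconstruction: disease annotations; all 43 targets inflammation-linked, remainder deterministic
disease	target_id
inflammation	HMGCR
inflammation	AKR1B1
inflammation	ALOX15
inflammation	ALOX5
inflammation	BIRC5
inflammation	CCL2
inflammation	CD40LG
inflammation	CDK2
inflammation	BCHE
inflammation	CXCL10
inflammation	CXCL2
inflammation	CYP1A2
inflammation	EGFR
inflammation	SELE
inflammation	GSK3B
inflammation	HMOX1
inflammation	CHUK
inflammation	IKBKB
inflammation	ICAM1
inflammation	IL1A
inflammation	IL1B
inflammation	IL10
inflammation	IL2
inflammation	IL6
inflammation	IL8
inflammation	MAPK14
inflammation	MAPK8
inflammation	CHRM1
inflammation	NFKBIA
inflammation	NOS3
inflammation	ODC1
inflammation	SPP1
inflammation	PPARA
inflammation	PPARD
inflammation	PPARG
inflammation	PLA2G1B
inflammation	PARP1
inflammation	COX1
inflammation	COX2
inflammation	STAT1
inflammation	JUN
inflammation	RELA
inflammation	TNF
lung disease	HMGCR
lung disease	EGFR
lung disease	IL8
lung disease	PARP1
arthritis	AKR1B1
arthritis	SELE
arthritis	MAPK14
arthritis	COX1
cancer	ALOX15
cancer	GSK3B
cancer	MAPK8
cancer	COX2
atherosclerosis	ALOX5
atherosclerosis	HMOX1
atherosclerosis	CHRM1
atherosclerosis	STAT1
diabetes mellitus	BIRC5
diabetes mellitus	CHUK
diabetes mellitus	NFKBIA
diabetes mellitus	JUN
cardiovascular disease	CCL2
cardiovascular disease	IKBKB
cardiovascular disease	NOS3
cardiovascular disease	RELA
skin disease	CD40LG
skin disease	ICAM1
skin disease	ODC1
skin disease	TNF
Alzheimer's disease	CDK2
Alzheimer's disease	IL1A
Alzheimer's disease	SPP1
gastrointestinal disease	BCHE
gastrointestinal disease	IL1B
gastrointestinal disease	PPARA
viral infection	CXCL10
viral infection	IL10
viral infection	PPARD
autoimmune disease	CXCL2
autoimmune disease	IL2
autoimmune disease	PPARG
obesity	CYP1A2
obesity	IL6
obesity	PLA2G1B
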