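# reconstruction: 16 inflammation-related pathway memberships; printed constraints satisfied, remainder deterministic
pathway	target_id
Influenza A	HMGCR
Influenza A	AKR1B1
Influenza A	ALOX15
Influenza A	ALOX5
Influenza A	BIRC5
Influenza A	CCL2
Influenza A	CD40LG
Influenza A	CDK2
Influenza A	CXCL10
Influenza A	CXCL2
Influenza A	CYP1A2
Influenza A	EGFR
Influenza A	SELE
Influenza A	GSK3B
Influenza A	HMOX1
Influenza A	CHUK
Toll-like receptor signaling pathway	TNF
Toll-like receptor signaling pathway	RELA
Toll-like receptor signaling pathway	JUN
Toll-like receptor signaling pathway	IKBKB
Toll-like receptor signaling pathway	ICAM1
Toll-like receptor signaling pathway	IL1A
Toll-like receptor signaling pathway	IL1B
Toll-like receptor signaling pathway	IL10
Toll-like receptor signaling pathway	IL2
Toll-like receptor signaling pathway	IL6
Toll-like receptor signaling pathway	IL8
Toll-like receptor signaling pathway	MAPK14
Toll-like receptor signaling pathway	MAPK8
Toll-like receptor signaling pathway	CHRM1
NF-kappa B signaling pathway	COX2
NF-kappa B signaling pathway	TNF
NF-kappa B signaling pathway	RELA
NF-kappa B signaling pathway	ICAM1
NF-kappa B signaling pathway	PARP1
NF-kappa B signaling pathway	PPARG
NF-kappa B signaling pathway	NFKBIA
NF-kappa B signaling pathway	NOS3
NF-kappa B signaling pathway	ODC1
NF-kappa B signaling pathway	SPP1
NF-kappa B signaling pathway	PPARA
NF-kappa B signaling pathway	PPARD
MAPK signaling pathway	COX2
MAPK signaling pathway	PPARG
MAPK signaling pathway	TNF
MAPK signaling pathway	RELA
MAPK signaling pathway	PLA2G1B
MAPK signaling pathway	PARP1
MAPK signaling pathway	COX1
MAPK signaling pathway	STAT1
MAPK signaling pathway	JUN
MAPK signaling pathway	HMGCR
TNF signaling pathway	AKR1B1
TNF signaling pathway	ALOX15
TNF signaling pathway	ALOX5
TNF signaling pathway	BIRC5
TNF signaling pathway	CCL2
Rheumatoid arthritis	CD40LG
Rheumatoid arthritis	CDK2
Rheumatoid arthritis	CXCL10
Rheumatoid arthritis	CXCL2
Rheumatoid arthritis	CYP1A2
Chemokine signaling pathway	EGFR
Chemokine signaling pathway	SELE
Chemokine signaling pathway	GSK3B
Chemokine signaling pathway	HMOX1
Chemokine signaling pathway	CHUK
T cell receptor signaling pathway	IKBKB
T cell receptor signaling pathway	ICAM1
T cell receptor signaling pathway	IL1A
T cell receptor signaling pathway	IL1B
T cell receptor signaling pathway	IL10
Jak-STAT signaling pathway	IL2
Jak-STAT signaling pathway	IL6
Jak-STAT signaling pathway	IL8
Jak-STAT signaling pathway	MAPK14
Jak-STAT signaling pathway	MAPK8
HIF-1 signaling pathway	CHRM1
HIF-1 signaling pathway	NFKBIA
HIF-1 signaling pathway	NOS3
HIF-1 signaling pathway	ODC1
HIF-1 signaling pathway	SPP1
PI3K-Akt signaling pathway	PPARA
PI3K-Akt signaling pathway	PPARD
PI3K-Akt signaling pathway	PPARG
PI3K-Akt signaling pathway	PLA2G1B
PI3K-Akt signaling pathway	PARP1
NOD-like receptor signaling pathway	COX1
NOD-like receptor signaling pathway	COX2
NOD-like receptor signaling pathway	STAT1
NOD-like receptor signaling pathway	JUN
NOD-like receptor signaling pathway	RELA
Inflammatory bowel disease	TNF
Inflammatory bowel disease	HMGCR
Inflammatory bowel disease	AKR1B1
Inflammatory bowel disease	ALOX15
Inflammatory bowel disease	ALOX5
Apoptosis	BIRC5
Apoptosis	CCL2
Apoptosis	CD40LG
Apoptosis	CDK2
Apoptosis	CXCL10
TGF-beta signaling pathway	CXCL2
TGF-beta signaling pathway	CYP1A2
TGF-beta signaling pathway	EGFR
TGF-beta signaling pathway	SELE
TGF-beta signaling pathway	GSK3B
Leukocyte transendothelial migration	HMOX1
Leukocyte transendothelial migration	CHUK
Leukocyte transendothelial migration	IKBKB
Leukocyte transendothelial migration	ICAM1
Leukocyte transendothelial migration	IL1A
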