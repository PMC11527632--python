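TLSRG_ALL	all 23 TLS-related genes	CCL18	CCL19	CCL20	CCL21	CXCL9	CXCL13	CCR5	CXCR3	IL10	CSF2	CD200	GFI1	IRF4	STAT5A	ICOS	CD38	CD40	SH2D1A	TIGIT	PDCD1	IL2RA	IL1R2	FBLN7
TLSRG_CHEMOKINE	chemokine	CCL18	CCL19	CCL20	CCL21	CXCL9	CXCL13
TLSRG_CHEMOKINE_RECEPTOR	chemokine receptor	CCR5	CXCR3
TLSRG_CYTOKINE	cytokine	IL10	CSF2
TLSRG_TRANSCRIPTION_FACTOR	transcription factor	CD200	GFI1	IRF4	STAT5A
TLSRG_COSTIMULATORY	co-stimulatory molecule	ICOS	CD38	CD40	SH2D1A
TLSRG_INHIBITORY_RECEPTOR	inhibitory receptor	TIGIT	PDCD1
TLSRG_CYTOKINE_RECEPTOR	cytokine receptor	IL2RA	IL1R2
TLSRG_ECM	ECM-associated molecule	FBLN7
TLSRG_FAVORABLE	favorable prognosis (high expression, HR<1)	CD200	CCR5	CCL21	CCL19	CCL18	CD38	ICOS	STAT5A	TIGIT	PDCD1	IRF4	IL10	IL2RA	IL1R2	SH2D1A	GFI1	FBLN7	CXCR3	CXCL13	CXCL9
TLSRG_ADVERSE	adverse prognosis (high expression, HR>1)	CD40	CSF2	CCL20
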