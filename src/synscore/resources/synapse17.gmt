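SYNAPSE_17	synapse-related 17-gene prognostic signature for glioma	PFN1	SHANK2	CACNG2	TNR	SHISA7	CHRNB2	GRIN3A	MAPK8IP2	GRID1	UNC13A	LRP4	SYBU	SLC16A3	DRP2	GRIK4	GRIN2C	IGSF21
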