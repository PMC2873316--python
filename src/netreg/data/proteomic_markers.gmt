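proteomic_markers	over-abundant lesional proteins	KRT17	KRT14	KRT16	SERPINB4	SERPINB3	ENO1	SOD2	LGALS7B	S100A9	S100A7
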