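SPSM	stress-response tumor cell / pDC prognostic model risk genes	STEAP4	TTC6	FMO1	ARHGEF38	BRINP3	ABCA12	TCIM	GRB7	TRIM17	EAF2
SPSM_IPSM_SHARED	risk genes common to the SPSM and IPSM models	FMO1	BRINP3	TCIM	TRIM17	EAF2
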