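# Synthetic stand-in for a proliferation / G2M-checkpoint signature.
proliferation	MKI67
proliferation	TOP2A
proliferation	CCNB1
proliferation	CCNB2
proliferation	CDK1
proliferation	BUB1
proliferation	AURKA
proliferation	AURKB
proliferation	PLK1
proliferation	UBE2C
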