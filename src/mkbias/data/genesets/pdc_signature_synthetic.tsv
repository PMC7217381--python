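# Synthetic stand-in for a plasmacytoid dendritic cell signature, used
# to flag the contaminant cluster among CD34+ lin- sorted cells.
pdc	IRF7
pdc	IRF8
pdc	LILRA4
pdc	CLEC4C
pdc	IL3RA
pdc	GZMB
pdc	JCHAIN
pdc	TCF4
pdc	SPIB
pdc	PLD4
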