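ZIK	GTPEFMAPE(L/V)Y
MEKK	G(T/S)PX(W/Y/F)MAPEV
Raf	GTXX(W/Y)MAPE
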