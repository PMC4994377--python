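name	category	iupac	description
ABRE	hormone	ACGTGKC	abscisic acid responsive element
DRE-CRT	stress	RCCGAC	dehydration/cold responsive element
GARE	hormone	TAACAAR	gibberellin responsive element
ERE	hormone	ATTTCAAA	ethylene responsive element
LTR	stress	CCGAAA	low-temperature responsive element
MBS	stress	CAACTG	MYB binding site, drought inducible
TC-rich	stress	ATTTTCTTCA	defense and stress responsive element
W-box	stress	TTGACC	WRKY binding site, wound/pathogen responsive
TATA-box	core	TATAWAW	core promoter element
CAAT-box	core	CCAAT	common enhancer element
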