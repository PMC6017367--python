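element	consensus	category
Box4	ATTAAT	light
G-box	CACGTG	light
GT1-motif	GGTTAA	light
ABRE	ACGTG	stress
MBS	CAACTG	stress
TC-rich	ATTCTCTAAC	stress
CGTCA-motif	CGTCA	MeJA
TGACG-motif	TGACG	MeJA
TCA-element	CCATCTTTTT	salicylic-acid
GARE-motif	TCTGTTG	gibberellin
P-box	CCTTTTG	gibberellin
TGA-element	AACGAC	auxin
ERE	ATTTCAAA	ethylene
circadian	CAANNNNATC	circadian
CAT-box	GCCACT	meristem
HSE	AAAAAATTTC	heat
LTR	CCGAAA	low-temperature
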