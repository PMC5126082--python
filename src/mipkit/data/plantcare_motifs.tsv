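# Cis-regulatory element consensus table, v1 (PlantCARE-style definitions).
# IUPAC nucleotide codes; category in {light, hormone, stress, circadian, other}.
name	consensus	category
Box-4	ATTAAT	light
G-Box	CACGTG	light
I-Box	GATAAGR	light
ACE	GACACGTATG	light
ARE	AAACCA	stress
HSE	AAAAAATTTC	stress
ABRE	ACGTGGC	hormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
W-box	TTGACC	stress
TC-rich_repeat	ATTTTCTTCA	stress
TCA-element	CCATCTTTTT	hormone
AuxRR-core	GGTCCAT	hormone
ERE	ATTTCAAA	hormone
GARE-motif	TCTGTTG	hormone
circadian	CAANNNNATC	circadian
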