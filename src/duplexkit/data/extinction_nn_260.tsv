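kind	key	epsilon
monomer	A	15340
monomer	C	7600
monomer	G	12160
monomer	U	10210
dimer	AA	13650
dimer	AC	10670
dimer	AG	12790
dimer	AU	12140
dimer	CA	10670
dimer	CC	7520
dimer	CG	9390
dimer	CU	8370
dimer	GA	12920
dimer	GC	9190
dimer	GG	11430
dimer	GU	10960
dimer	UA	12520
dimer	UC	8900
dimer	UG	10400
dimer	UU	10110
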