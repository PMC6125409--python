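# Text-named cross-linked lysine pairs with SDS-PAGE bands of origin.
residue_a	residue_b	bands	construct
61	218	monomer	EX
65	77	monomer	EX
77	151	monomer,dimer	EX
77	168	dimer	EX
77	299	dimer	FL
129	129	dimer	EX
129	151	dimer	EX
129	296	dimer	FL
129	299	dimer	FL
155	168	dimer	EX
155	218	dimer	EX
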