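Ccr1
Ccr2
Cxcr2
Cxcr4
Cxcr6
Csf1r
Csf2ra
Csf2rb
Ifngr1
Ifngr2
Cd74
Ighm
Clec4a2
Clec4a3
Il6ra
Il6st
Il1r1
Il1r2
Tnfrsf1a
Tnfrsf1b
Il10ra
Il10rb
Igf1r
Plaur
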