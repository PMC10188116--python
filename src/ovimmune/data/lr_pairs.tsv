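ligand	receptor
Ccl2	Ccr2
Ccl7	Ccr2
Ccl8	Ccr2
Ccl12	Ccr2
Ccl3	Ccr5
Ccl4	Ccr5
Ccl5	Ccr5
Ccl8	Ccr5
Ccl3	Ccr1
Ccl5	Ccr1
Ccl7	Ccr1
Ccl9	Ccr1
Ccl19	Ccr7
Ccl21a	Ccr7
Ccl20	Ccr6
Ccl19	Ccrl2
Cxcl1	Cxcr2
Cxcl2	Cxcr2
Cxcl3	Cxcr2
Cxcl5	Cxcr2
Cxcl9	Cxcr3
Cxcl10	Cxcr3
Cxcl11	Cxcr3
Cxcl12	Cxcr4
Cxcl16	Cxcr6
Il1a	Il1r1
Il1b	Il1r1
Il1rn	Il1r1
Il1a	Il1r2
Il1b	Il1r2
Il18	Il18r1
Il2	Il2rb
Il4	Il4ra
Il6	Il6ra
Il7	Il7r
Il10	Il10ra
Il13	Il13ra1
Il15	Il15ra
Tnf	Tnfrsf1a
Tnf	Tnfrsf1b
Ifng	Ifngr1
Csf1	Csf1r
Csf2	Csf2ra
Tgfb1	Tgfbr1
Tgfb1	Tgfbr2
Inhba	Acvr2a
Gdf11	Acvr2a
Gdf11	Tgfbr1
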