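type	gene
CM	Ly6c2
CM	Ccr2
CM	Chil3
CM	Plac8
CM	F13a1
NCM	Ace
NCM	Ear2
NCM	Treml4
NCM	Eno3
NCM	Spn
cDC2	Cd209a
cDC2	Clec10a
cDC2	H2-DMb2
cDC2	Ifitm1
mcDC2	Ccr7
mcDC2	Fscn1
mcDC2	Ccl22
mcDC2	Il4i1
Neutrophil	S100a8
Neutrophil	S100a9
Neutrophil	Retnlg
Neutrophil	Mmp9
NK	Ncr1
NK	Klrb1c
NK	Gzma
NK	Eomes
RPM	Vcam1
RPM	Spic
RPM	Hmox1
RPM	Slc40a1
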