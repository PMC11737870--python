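Mki67
Top2a
Ccnb1
Ccnb2
Ccna2
Ccne1
Ccne2
Ccnd1
Cdk1
Cdk4
Cdk6
Cdc20
Cdc25c
Cdca3
Cdca8
Plk1
Bub1
Bub1b
Aurka
Aurkb
Birc5
Mcm2
Mcm3
Mcm4
Mcm5
Mcm6
Mcm7
Pcna
Rrm1
Rrm2
Tyms
Tk1
E2f1
Foxm1
Cenpa
Cenpe
Cenpf
Kif11
Kif23
Nusap1
Ube2c
Tpx2
Hmgb2
Stmn1
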