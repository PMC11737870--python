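IFNG_RESPONSE	illustrative subset	Stat1	Gbp2	Gbp3	Gbp4	Cxcl9	Cxcl10	Irf1	Acod1	Ly6a	Ifitm3	Socs3	Tap1	Psmb9	Ciita	Il18bp
IFNA_RESPONSE	illustrative subset	Ifit1	Ifit3	Isg15	Irf7	Oasl1	Oasl2	Mx1	Mx2	Rsad2	Usp18	Ifi27	Bst2
IL6_JAK_STAT3	illustrative subset	Socs3	Il6ra	Stat3	Osmr	Il4ra	Junb	Myd88	Cd14	Pim1	Ifngr1
HEME_METABOLISM	illustrative subset	Hmox1	Slc40a1	Spic	Alas2	Blvrb	Fech	Slc4a1	Epor	Gypa	Tfrc
E2F_TARGETS	illustrative subset	E2f1	Mki67	Mcm2	Mcm3	Mcm5	Pcna	Rrm2	Tyms	Ccne1	Cdk1	Birc5
G2M_CHECKPOINT	illustrative subset	Ccnb1	Ccnb2	Cdk1	Top2a	Aurka	Aurkb	Plk1	Bub1	Cdc20	Ube2c
COMPLEMENT	illustrative subset	C1qa	C1qb	C1qc	C3	C3ar1	Cfb	Cfp	Serping1	Itgam	Cd55
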