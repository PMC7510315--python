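# Published driver-gene mutation frequencies: Chinese ccRCC cohort (n=55) vs
# TCGA KIRC white subcohort (Fisher denominators consistent with n=451).
# Columns: gene, percent mutated in the Chinese cohort, percent mutated in the
# TCGA white subcohort (one decimal as printed), published two-sided Fisher p.
gene	freq_chinese_pct	freq_tcga_pct	published_p
VHL	76.4	52.8	0.000862049
BAP1	18.2	9.0	0.053248208
NCOR2	12.7	1.4	0.000127079
SETD2	10.9	11.0	1
PBRM1	9.1	33.7	8.38E-05
ATM	9.1	3.5	0.065990135
ERBB3	9.1	1.9	0.011804502
NBN	9.1	0.4	0.000226619
DNM2	9.1	0.2	7.06E-05
PTEN	7.3	4.3	0.299167676
KMT2C	7.3	3.8	0.269293981
GOLGA5	7.3	1.1	0.010440507
MTOR	5.5	7.1	1
FAT1	5.5	3.5	0.449134307
PTCH1	5.5	2.1	0.131792795
MSH6	5.5	1.1	0.045880562
PTPRB	5.5	0.9	0.031041033
EXT2	5.5	0.4	0.01040418
APC	3.6	1.1	0.170756605
KDR	3.6	1.1	0.170756605
XPC	3.6	1.1	0.170756605
TSC1	3.6	0.9	0.13083787
FGFR4	3.6	0.7	0.093628013
SH2B3	3.6	0.4	0.06033848
TGFBR2	3.6	0.4	0.06033848
FANCE	1.8	4.3	0.711854112
PIK3CA	1.8	4.0	0.70899921
TP53	1.8	3.3	1
POLE	1.8	3.1	1
CHD4	1.8	2.6	1
SMARCA4	1.8	2.3	1
ATR	1.8	2.1	1
CDK12	1.8	2.1	1
TET2	1.8	2.1	1
CHEK2	1.8	1.9	1
EGFR	1.8	1.9	1
BLM	1.8	1.6	0.604409035
FLT4	1.8	1.6	0.604409035
GNAS	1.8	1.6	0.604409035
MYH11	1.8	1.6	0.604409035
TRRAP	1.8	1.6	0.604409035
NCOR1	1.8	1.4	0.55540565
PIK3CB	1.8	1.4	0.55540565
FBXW7	1.8	1.1	0.500455786
GATA2	1.8	1.1	0.500455786
KAT6B	1.8	1.1	0.500455786
MLLT4	1.8	1.1	0.500455786
TCF12	1.8	1.1	0.500455786
ERBB2	1.8	0.9	0.4388528
ARID1B	1.8	0.9	0.4388528
ASXL1	1.8	0.9	0.4388528
CIC	1.8	0.9	0.4388528
JAK3	1.8	0.9	0.4388528
MECOM	1.8	0.9	0.4388528
NUP98	1.8	0.9	0.4388528
PER1	1.8	0.9	0.4388528
BARD1	1.8	0.7	0.369807843
DDR2	1.8	0.7	0.369807843
MET	1.8	0.7	0.369807843
NDRG1	1.8	0.4	0.292440502
FANCG	1.8	0.4	0.292440502
PLCG1	1.8	0.4	0.292440502
PMS2	1.8	0.4	0.292440502
PRF1	1.8	0.2	0.205768403
CEBPA	1.8	0.2	0.205768403
MAP2K1	1.8	0.2	0.205768403
MYH9	1.8	0.2	0.205768403
PRDM1	1.8	0.2	0.205768403
TCF7L2	1.8	0.2	0.205768403
FH	1.8	0.0	0.108695652
CDKN1B	1.8	0.0	0.108695652
KLF6	1.8	0.0	0.108695652
PPM1D	1.8	0.0	0.108695652
TRAF7	1.8	0.0	0.108695652
KDM5C	0.0	6.9	0.037678184
ARID1A	0.0	5.5	0.095406442
MALAT1	0.0	2.1	0.606792113
FGFR3	0.0	1.4	1
ABL2	0.0	1.1	1
BCL6	0.0	1.1	1
CDK4	0.0	0.9	1
CDH1	0.0	0.7	1
PALB2	0.0	0.7	1
FANCF	0.0	0.2	1
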