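# Genes recurrently mutated in myeloid malignancies (MDS / sAML panel);
# used to label simulated driver mutations and to count drivers in reports.
ASXL1
BCOR
BCORL1
CALR
CBL
CEBPA
CSNK1A1
CUX1
DDX41
DNMT3A
ETV6
EZH2
FLT3
GATA2
GNAS
IDH1
IDH2
JAK2
KIT
KMT2D
KRAS
MPL
NF1
NPM1
NRAS
PHF6
PPM1D
PTPN11
RAD21
RUNX1
SETBP1
SF3B1
SMC1A
SMC3
SRSF2
STAG2
TET2
TP53
U2AF1
WT1
ZRSR2
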