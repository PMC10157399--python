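# Published candidate-variant table driving the reanalysis benchmarks:
# 56 rare variants in 36 DD/ID genes from 53 affected individuals, identified
# by literature-driven whole-word re-queries of a 5,459-exome store.
# Columns: delay is months from positive query to diagnostic report ("." =
# not determined / shared with the row above); n_patients is stated once per
# patient group; classification is the final call (P/LP/VUS/LB); retro_label
# and retro_criteria transcribe the retrospective evidence-code cell ("." = NA).
gene	delay_months	segregation	genomic_position	protein_change	n_patients	classification	retro_label	retro_criteria
CSNK2B	4	De novo	chr6:g.31637615T>C	p.(Leu187Pro)	1	LP	VUS	PM1,PM2,PP5,BP1
DLL1	2	De novo	chr6:g.170594361del	p.(Lys338Argfs*28)	1	LP	.	.
GRIA2	2	De novo	chr4:g.158282245G>A	p.(Gly792Glu)	1	LP	LP	PM1,PM2,PM5,PP2
KCNN2	2	De novo	chr5:g.113808863T>C	p.?	1	VUS	.	.
MAPK8IP3	2	De novo	chr16:g.1812844C>T	p.(Arg578Cys)	2	P	LP	PM1,PM2,PP3,PP5
MAPK8IP3	8	ND	chr16:g.1813786T>G	p.?	.	VUS	.	.
MN1	1	De novo	chr22:g.28147072del	p.(Pro1265Leufs*55)	1	P	.	.
NFASC	3	Paternally and maternally inherited	chr1:g.204943318C>T	p.(Arg431Trp)	1	VUS	VUS	PM1
SMPD4	3	Maternally inherited	chr2:g.130914172del	p.Ala431Hisfs*9	1	LP	.	.
SMPD4	.	Paternally inherited	chr2:g.130914204_130914206del	p.Phe419del	.	LP	.	.
SUZ12	6	Maternally inherited	chr17:g.30320326C>T	p.(Arg423*)	2	LP	.	.
SUZ12	.	Paternally inherited	chr17:g.30264544G>A	p.?	.	VUS	.	.
TAOK1	3	Maternally inherited	chr17:g.27816684G>T	p.(Glu220*)	1	LP	.	.
TAOK1	7	De novo	chr17:g.27809240A>C	p.(Met197Leu)	1	LP	VUS	PM1,PM2
TAOK2	1	Paternally inherited	chr16:g.29998795A>T	p.(Arg1068*)	1	VUS	.	.
WDFY3	3	Paternally inherited	chr4:g.85687036_85687037del	p.(Lys1705Argfs*10)	1	LP	.	.
BAZ2B	2	Maternally inherited	chr2:g.160287462dup	p.(Ser703Leufs*9)	1	VUS	.	.
BRD4	10	De novo	chr19:g.15374283T>C	p.(Tyr430Cys)	1	LP	VUS	PM1,PM2,PP2
CDC42BPB	3	Maternally inherited	chr14:g.103440469G>A	p.(Arg509*)	3	VUS	.	.
CDC42BPB	11	Paternally inherited	chr14:g.103410506T>C	p.Gln1377Arg	.	LB	VUS	PM1,PM2
CDC42BPB	11	Paternally inherited	chr14:g.103432620A>T	p.Leu859Gln	.	LB	VUS	PM2
CUL3	2	De novo	chr2:g.225368388dup	p.(Asn453Lysfs*5)	3	VUS	.	.
CUL3	.	Maternally inherited	chr2:g.225365152C>T	p.(Trp513*)	.	VUS	.	.
CUL3	3	Maternally inherited	chr2:g.225370672C>A	p.?	.	VUS	.	.
FBRSL1	2	Paternally inherited	chr12:g.133158105G>T	p.?	2	LB	.	.
FBRSL1	6	ND	chr12:g.133067271G>T	p.(Glu39*)	.	LB	.	.
HPDL	2	Paternally and maternally inherited	chr1:g.45793608C>T	p.(Thr263Met)	2	LP	VUS	PM1,PP3,PP5
HPDL	.	Paternally and maternally inherited	chr1:g.45793162_45793165dup	p.(Ala116Cysfs*81)	.	LP	.	.
JARID2	2	Maternally inherited	chr6:g.15501555G>A	p.(Arg788Gln)	1	VUS	VUS	PM1,PP3,BP1
JMJD1C	9	Maternally inherited	chr10:g.64974008del	p.(Pro640Hisfs*10)	1	VUS	.	.
KMT2D	2	Maternally inherited	chr12:g.49427884T>C	p.(Glu3569Gly)	1	LP	VUS	PM2,BP1
LMBRD2	1	De novo	chr5:g.36115212G>A	p.(Arg483Cys)	1	LP	VUS	PM2,PP5
LMNB1	2	Maternally inherited	chr5:g.126140563C>T	p.(Ala152Val)	1	LB	LP	PM1,PM2,PM5
MPP5	3	Maternally inherited	chr14:g.67779336A>G	p.(Ile378Met)	1	LB	VUS	PM1,PM2,BP4
NR4A2	.	Not maternally inherited	chr2:g.157186374del	p.(Gln109Serfs*5)	1	LP	.	.
NUP188	8	Paternally and maternally inherited	chr9:g.131745626del	p.(Cys617Trpfs*2)	1	LP	.	.
NUP188	.	Paternally and maternally inherited	chr9:g.131760903G>A	p.?	.	LP	.	.
SCAF4	2	Paternally inherited	chr21:g.33065654_33065657del	p.(Arg488Asnfs*10)	2	VUS	.	.
SCAF4	.	Maternally inherited	chr21:g.33043941_33043944del	p.(Glu1071Glyfs*12)	.	VUS	.	.
SETD1A	2	ND	chr16:g.30976565del	p.(Lys502Serfs*159)	1	VUS	.	.
SLC12A2	5	Paternally inherited	chr5:g.127512826C>G	p.(Gln987Glu)	1	LB	VUS	PM1,PM2,BP1
SOX4	6	Paternally inherited	chr6:g.21595127C>G	p.Ala121Gly	1	VUS	LP	PM1,PM2,PP2,PP3
SYT1	1	Maternally inherited	chr12:g.79837973T>A	p.(Phe350Tyr)	1	VUS	VUS	PM1,PM2,PP2
TET3	.	Paternally inherited	chr2:g.74314995C>A	p.(Cys906*)	1	LP	.	.
TET3	8	Paternally inherited	chr2:g.74320729C>G	p.(Ala1068Gly)	1	LB	VUS	PM1,PM2
TNRC6B	10	Paternally inherited	chr22:g.40696947C>T	p.Gln1292*	1	VUS	.	.
TOMM70	1	Paternally inherited	chr3:g.100086949T>C	p.(Ile538Val)	1	LB	VUS	PM1,PM2
TOMM70	10	Maternally inherited	chr3:g.100087956del	p.(Phe492Leufs*112)	1	VUS	.	.
TTC5	3	Paternally inherited	chr14:g.20757884G>A	p.(Arg409*)	1	LP	.	.
TTC5	.	Maternally inherited	chr14:g.20763470C>T	p.?	.	LP	.	.
ZNF292	2	De novo	chr6:g.87969507_87969508del	p.(Glu2054Lysfs*14)	6	LP	.	.
ZNF292	.	De novo	chr6:g.87966666C>T	p.(Arg1107*)	.	LP	.	.
ZNF292	1	Maternally inherited	chr6:g.87968280C>T	p.(Gln1645*)	.	VUS	.	.
ZNF292	2	Probable paternal inheritance	chr6:g.87925776G>A	p.?	.	VUS	.	.
ZNF292	.	Not maternally inherited	chr6:g.87970807del	p.(Leu2487Cysfs*6)	.	VUS	.	.
ZNF292	.	Maternally inherited	chr6:g.87970961del	p.(Asn2538Lysfs*21)	.	LB	.	.
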