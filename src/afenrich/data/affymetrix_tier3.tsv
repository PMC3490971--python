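gene	substitution	rsid	chrom	pos	ref	alt	phenotype	qe7_freq	qa149_freq
PPARG	Pro12Ala	rs1801282	3	12393125	C	G	Type 2 diabetes	0.07	0.05
PON2	Ser311Cys	rs7493	7	95034775	G	C	Coronary artery disease	0.29	0.28
NAT2	Arg197Gln	rs1799930	8	18258103	G	A	Slow metabolism of clonazepam	0.14	0.23
MTR	Asp473Gly	rs1805087	1	237048500	A	G	Cardiovascular disease	0.29	0.22
NQO1	Pro187Ser	rs1800566	16	69745145	G	A	Benzene poisoning risk; colorectal cancer; breast cancer survival	0.14	0.21
ULK4	Lys569Arg	rs3774372	3	41877414	T	C	Diastolic blood pressure	0.57	0.19
CDC6	Val441Ile	rs13706	17	38457151	G	A	Decline rate in ex-smokers with COPD	0.29	0.14
PARP1	Val762Ala	rs1136410	1	226555302	A	G	Cancer risk (direction differs by ancestry)	0.14	0.13
BDNF	Val66Met	rs6265	11	27679916	C	T	Anxiety, depression disorders, motor function	0.07	0.11
PPP1R3A	Asp905Tyr	rs1799999	7	113518434	C	A	Type 2 diabetes, insulin resistance	0.14	0.10
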