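gene	substitution	rsid	chrom	pos	ref	alt	qe7_freq	qt86_freq	EUR_freq	ASN_freq	AFR_freq	AMR_freq
BMP4	Val152Ala	rs17563	14	54417522	A	G	0.64	0.41	0.56	0.27	0.19	0.34
ZNF229	Gly662Arg	rs1434579	19	44932972	C	T	0.57	0.21	0.36	0.32	0.03	0.22
ULK4	Lys569Arg	rs3774372	3	41877414	T	C	0.57	0.34	0.20	0.15	0.23	0.15
AKAP13	Gly624Val	rs745191	15	86123170	G	T	0.43	0.27	0.31	0.02	0.01	0.19
FMO2	Ser195Leu	rs2020862	1	171168584	C	T	0.71	0.51	0.25	0.48	0.39	0.38
COL4A3	Asp326Tyr	rs55703767	2	228121101	G	T	0.43	0.21	0.23	0.11	0.01	0.14
UTS2	Thr21Met	rs228648	1	7913430	G	A	0.79	0.71	0.58	0.32	0.46	0.44
ACAT2	Lys211Arg	rs25683	6	160196343	A	G	0.64	0.48	0.56	0.15	0.14	0.49
TTC37	Arg1296Ser	rs2303650	5	94826655	C	A	0.71	0.28	0.17	0.13	0.38	0.24
PDZRN4	Gly171Ser	rs285584	12	41946539	G	A	0.57	0.22	0.16	0.11	0.24	0.14
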