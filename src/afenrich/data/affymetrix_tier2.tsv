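gene	substitution	rsid	chrom	pos	ref	alt	phenotype	qe7_freq	qa149_freq
HMCN1	Gln4437Arg	rs10911825	1	186101539	A	G	Age related macular degeneration	0.50	0.43
IKBKAP	Cys1072Ser	rs3204145	9	111651620	A	T	Familial dysautonomia	0.14	0.27
VSX1	Arg217His	rs6138482	20	25059442	C	T	Keratoconus, polymorphous corneal dystrophy	0.21	0.19
EVC	Gln74Pro	rs2291157	4	5721021	A	C	Ellis-van Creveld syndrome; Weyers acrodental dysostosis	0.07	0.17
SGCG	Arg116His	rs17314986	13	23824818	G	A	Muscular dystrophy, limb-girdle, type 2c	0.07	0.16
SACS	Asn232Lys	rs2031640	13	23930055	A	T	Spastic ataxia, Charlevoix-Saguenay type	0.07	0.11
OSMR	Glu527Lys	rs10941412	5	38919158	G	A	Primary cutaneous amyloidosis	0.14	0.10
ARHGEF10	Ser980Ala	rs17683288	8	1877480	T	G	Slow nerve conduction velocity	0.14	0.09
CACNA1S	Arg1539Cys	rs3850625	1	201016296	G	A	Periodic paralysis, malignant hyperthermia	0.07	0.08
RSPH4A	Asn627His	rs9488991	6	116951678	A	C	Ciliary dyskinesia, primary	0.07	0.05
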