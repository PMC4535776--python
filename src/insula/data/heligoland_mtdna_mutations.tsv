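# New mitochondrial point mutations in the Heligoland house-mouse cohort
# (11 full mitogenomes carrying the colonizing haplotypes; positions are
# 1-based coordinates on the NCBI37/mm9 chrM reference, control region
# excluded). The consensus is the cohort consensus; "fixed_carriers" are
# animals with an unambiguous derived base, "het_carriers" show a double
# peak (consensus + derived). The six rightmost columns give the base
# carried by comparator species at the homologous position.
position	region	consensus	derived	fixed_carriers	het_carriers	Rat	Human	Orangutan	Dog	Horse	Opossum
1080	tRNA-Val	A	T	HG_01	.	A	A	A	T	A	T
4771	ND2	C	A	HG_02	.	C	C	C	T	A	A
5157	tRNA-Asn	C	T	HG_05	.	C	C	C	C	C	C
5163	rep_ori	C	A	HG_06	.	C	C	C	C	C	C
10688	ND4	T	C	HG_10	.	C	A	T	A	A	A
10689	ND4	A	G	HG_12	.	A	A	A	A	A	C
12009	ND5	T	G	HG_08	HG_11	C	A	C	G	G	A
13681	ND6	C	T	HG_14	HG_13	A	C	C	G	A	C
14698	CYTB	T	C	HG_14	.	T	T	T	C	T	T
15163	CYTB	G	A	HG_10	.	G	G	G	G	G	G
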