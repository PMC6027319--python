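tissue	element	superfamily	class_label	log2fc	b_expansion
brain	AlRepD-1119	L2	LINE	1.4829	22/88/115/126/187
brain	CR1-28_HM	CR1	LINE	3.2887	No
brain	REX1-3_XT	Rex-Babar	LINE	1.7297	No
brain	GYPSY2-I_CB	Gypsy	LTR	5.2102	No
brain	AlRepC-299	Unknown	Unknown	1.5748	9/16/4/6/0
brain	I-6_AAe	I	LINE	3.6624	No
brain	L1-6_DR	L1	LINE	-3.8609	2/0/0/0/2
brain	BovBa-1_EF	RTE-BovB	LINE	4.1560	No
brain	AlRepD-1964	Unknown	Unknown	1.1420	24/117/121/120/160
brain	Gypsy-34-I_DR	Gypsy	LTR	4.5448	No
brain	AlRepD-520	Unknown	Unknown	1.8113	47/30/6/2/0
brain	Mariner-1_SP	TcMar-Fot1	DNA	4.0150	0/0/2/5/12
brain	ERV1-3N-EC_I-int	ERV1	LTR	2.4732	No
brain	Gypsy-17-I_DR	Gypsy	LTR	-1.7877	2/2/2/4/16
brain	Gypsy52-I_DR	Gypsy	LTR	5.4846	No
brain	Tc1-2Eso	TcMar-Tc1	DNA	2.4478	No
brain	Rex1-52_DR	Rex-Babar	LINE	-3.1220	No
brain	Helitron-2_DR	Helitron	RC	-1.2385	No
brain	RMER17C-int	ERVK	LTR	2.6684	No
brain	Gypsy-20-I_DR	Gypsy	LTR	-2.1144	0/0/2/0/0
muscle	AlRepC-299	Unknown	Unknown	7.5228	9/16/4/6/0
muscle	AlRepB-358	hAT-Ac	DNA	3.1883	207/209/146/139/11
muscle	Mariner-1_SP	TcMar-Fot1	DNA	11.0098	0/0/2/5/12
gonad_male	AlRepD-4130	hAT-Ac	DNA	2.7431	37/87/51/56/31
gonad_male	HEROTn	R2-Hero	LINE	-6.4246	No
gonad_male	7SLRNA	srpRNA	srpRNA	3.4512	No
gonad_male	P-27_HM	P	DNA	-2.5097	No
gonad_male	AgaP15	P	DNA	-5.8314	No
gonad_male	Charlie16	hAT-Charlie	DNA	-5.7227	No
gonad_male	AlRepE-134	DNA	DNA	-2.9391	6/3/3/5/3
gonad_male	ERV-4_CPB-I	ERV1	LTR	-2.9007	No
gonad_male	Gypsy-10_GA-LTR	Gypsy	LTR	-2.6009	No
gonad_male	AlRepE-2243	Unknown	Unknown	3.6990	5/2/2/0/2
gonad_male	CR1-20_CQ	CR1	LINE	-2.9297	No
gonad_male	Dada-1_ON	Dada	DNA	-3.1755	No
gonad_male	Copia3-I_XT	Copia	LTR	-5.6443	No
gonad_male	AlRepD-3555	Unknown	Unknown	-4.5855	No
gonad_female	AlRepD-1636	Unknown	Unknown	5.5199	23/94/96/104/111
gonad_female	hAT-27_LCh	DNA	DNA	3.0980	No
gonad_female	AlRepD-4141	Unknown	Unknown	6.7706	2/0/0/0/2
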