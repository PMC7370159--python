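gene	category	strand	size_lo	size_hi	gc_lo	gc_hi	aa_lo	aa_hi	start_codons	stop_codons	one_letter	anticodon	igs_lo	igs_hi
tRNA-Phe	tRNA	H	68	68	45.59	51.47			 	 	F	GAA	0	0
12S rDNA	rRNA	H	951	954	47.79	49.21			 	 	 	 	0	0
tRNA-Val	tRNA	H	72	72	47.22	50.00			 	 	V	TAC	0	0
16S rDNA	rRNA	H	1716	1728	45.37	46.50			 	 	 	 	0	0
tRNA-Leu	tRNA	H	74	75	48.00	48.65			 	 	L	TAA	0	0
ND1	CDS	H	975	975	48.82	51.08	324	324	ATG	TAG,TAA	 	 	0	0
tRNA-Ile	tRNA	H	70	70	50.00	52.86			 	 	I	GAT	5	6
tRNA-Gln	tRNA	L	71	71	40.85	40.85			 	 	Q	TTG	-1	-1
tRNA-Met	tRNA	H	70	71	45.71	47.14			 	 	M	CAT	-1	-1
ND2	CDS	H	1045	1047	49.00	50.43	348	348	ATG	T,TAG	 	 	0	0
tRNA-Trp	tRNA	H	69	71	50.70	52.17			 	 	W	TCA	0	0
tRNA-Ala	tRNA	L	69	69	39.13	43.48			 	 	A	TGC	1	1
tRNA-Asn	tRNA	L	73	73	47.95	52.05			 	 	N	GTT	1	1
tRNA-Cys	tRNA	L	66	67	43.28	45.45			 	 	C	GCA	37	38
tRNA-Tyr	tRNA	L	70	70	45.71	47.14			 	 	Y	GTA	0	0
COX1	CDS	H	1551	1551	45.07	47.58	516	516	GTG	TAA	 	 	1	1
tRNA-Ser	tRNA	L	71	71	46.48	47.89			 	 	S	TGA	0	0
tRNA-Asp	tRNA	H	71	71	43.66	46.48			 	 	D	GTC	3	3
COX2	CDS	H	691	691	41.68	44.86	230	230	ATG	T	 	 	6	7
tRNA-Lys	tRNA	H	74	75	45.67	48.00			 	 	K	TTT	0	0
ATP8	CDS	H	165	168	44.64	49.70	55	55	ATG	TAA,TAG	 	 	1	1
ATP6	CDS	H	678	684	44.84	50.00	225	227	ATG,ATA	TAA	 	 	-10	-4
COX3	CDS	H	785	786	47.46	49.17	260	261	ATG	TA,TAA	 	 	-1	-1
tRNA-Gly	tRNA	H	69	70	32.86	36.23			 	 	G	TCC	0	0
ND3	CDS	H	349	351	47.85	49.00	115	116	ATG	T,TAG	 	 	0	0
tRNA-Arg	tRNA	H	67	69	29.85	37.68			 	 	R	TCG	0	0
ND4L	CDS	H	297	297	48.82	52.86	98	98	ATG	TAA	 	 	1	1
ND4	CDS	H	1381	1381	46.85	49.17	460	460	ATG	T	 	 	-7	-7
tRNA-His	tRNA	H	71	73	36.99	39.44			 	 	H	GTG	0	0
tRNA-Ser	tRNA	H	67	68	50.75	57.35			 	 	S	GCT	0	0
tRNA-Leu	tRNA	H	73	73	45.21	45.21			 	 	L	TAG	4	4
ND5	CDS	H	1839	1839	44.54	47.80	612	612	ATG	TAA,TAG	 	 	0	0
ND6	CDS	L	522	522	44.44	48.85	173	173	ATG	TAG,TAA	 	 	-4	-4
tRNA-Glu	tRNA	L	69	69	40.58	43.48			 	 	E	TTC	0	0
CYTB	CDS	H	1141	1141	46.71	49.69	380	380	ATG	T	 	 	4	4
tRNA-Thr	tRNA	H	72	72	52.78	58.33			 	 	T	TGT	0	0
tRNA-Pro	tRNA	L	71	71	38.03	45.07			 	 	P	TGG	-1	-1
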