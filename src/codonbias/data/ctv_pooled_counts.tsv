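# Cumulative codon counts over the full coding regions of 20 CTV
# isolates, with published RSCU for CTV and for Citrus sinensis.
amino_acid	codon	count	rscu_ctv	rscu_citrus
Phe	UUU	4888	1.26	1.05
Phe	UUC	2888	0.74	0.95
Leu	UUA	3748	1.57	0.77
Leu	UUG	4825	2.02	1.40
Leu	CUU	2149	0.90	1.58
Leu	CUC	1216	0.51	0.91
Leu	CUA	1053	0.44	0.53
Leu	CUG	1354	0.57	0.80
Val	GUU	5171	1.52	1.61
Val	GUC	2302	0.68	0.67
Val	GUA	1861	0.55	0.48
Val	GUG	4277	1.26	1.24
Ser	UCU	3742	1.50	1.38
Ser	UCC	2014	0.81	0.77
Ser	UCA	1642	0.66	1.33
Ser	UCG	3125	1.25	0.71
Ser	AGU	2791	1.12	0.87
Ser	AGC	1642	0.66	0.93
Pro	CCU	2261	1.62	1.31
Pro	CCC	984	0.71	0.87
Pro	CCA	845	0.61	1.25
Pro	CCG	1476	1.06	0.57
Thr	ACU	3455	1.74	1.45
Thr	ACC	1676	0.84	0.83
Thr	ACA	891	0.45	1.18
Thr	ACG	1933	0.97	0.53
Gly	GGU	4337	1.99	1.13
Gly	GGC	1311	0.60	0.99
Gly	GGA	1329	0.61	1.07
Gly	GGG	1759	0.81	0.81
Gln	CAA	1603	1.24	1.06
Gln	CAG	986	0.76	0.94
His	CAU	1535	1.03	1.08
His	CAC	1453	0.97	0.92
Asn	AAU	2997	1.00	1.07
Asn	AAC	2992	1.00	0.93
Lys	AAA	3604	0.94	0.86
Lys	AAG	4077	1.06	1.14
Asp	GAU	4988	1.10	1.29
Asp	GAC	4101	0.90	0.71
Glu	GAA	4188	1.12	0.95
Glu	GAG	3262	0.88	1.05
Arg	AGA	2080	1.13	1.82
Arg	AGG	2032	1.11	1.82
Arg	CGU	2814	1.53	0.68
Arg	CGC	1599	0.87	0.56
Arg	CGA	1343	0.73	0.58
Arg	CGG	1136	0.62	0.54
Cys	UGU	2235	1.24	0.98
Cys	UGC	1356	0.76	1.02
Tyr	UAU	2500	0.89	1.05
Tyr	UAC	3107	1.11	0.95
Ala	GCU	3824	1.68	1.58
Ala	GCC	1558	0.68	0.86
Ala	GCA	1373	0.60	1.11
Ala	GCG	2373	1.04	0.45
Ile	AUU	2562	1.21	1.37
Ile	AUC	1681	0.79	0.93
Ile	AUA	2135	1.00	0.70
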