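anticodon	amino_acid	codon	re_u	sd_u	re_c	sd_c	re_a	sd_a	re_g	sd_g	mod_fraction	printed_ratio
AAA	Phe	UUU	3.2	0.3	BD		NE		NE		0.0
AAG	Leu	CUU	4.3	0.4	1.5	0.1	BD		BD		0.15	76:24
AAU	Ile	AUU	4.5	0.5	0.43	0.1	BD		0.27	0.03	0.0
AAC	Val	GUU	0.84	0.1	0.59	0.04	BD		0.35	0.06	0.0	59:41
AGA	Ser	UCU	19.7	1.0	1.4	0.2	BD		BD		0.0
AGG	Pro	CCU	12.9	1.1	10.3	0.5	0.92	0.1	1.0	0.04	0.0	56:44
AGU	Thr	ACU	10.7	0.5	1.4	0.2	BD		BD		0.0
AGC	Ala	GCU	1.3	0.1	1.2	0.1	BD		BD		0.0	52:48
AUG	His	CAU	6.1	0.4	2.9	0.1	BD		NE		0.5	68:32
AUU	Asn	AAU	7.2	0.4	BD		BD		BD		0.0
AUC	Asp	GAU	3.5	0.5	BD		BD		BD		0.0
ACA	Cys	UGU	3.6	0.1	BD		NE		NE		0.0	≥95:5
ACG	Arg	CGU	7.6	0.5	6.1	0.3	0.91	0.1	BD		1.0	55:45
ACU	Ser	AGU	9.4	0.8	BD		BD		0.36	0.04	0.0	≥95:5
ACC	Gly	GGU	1.3	0.3	0.40	0.1	BD		0.33	0.01	0.0	76:24
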