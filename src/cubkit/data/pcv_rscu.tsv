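# Published pooled ORF12 RSCU values for Chinese porcine circovirus
# species PCV-1..PCV-4 and the Sus scrofa host reference usage.
# Columns: amino acid, codon (RNA alphabet), RSCU per dataset.
aa	codon	PCV1	PCV2	PCV3	PCV4	Sus_scrofa
F	UUU	1.13	1.15	1.08	0.87	0.93
F	UUC	0.87	0.85	0.92	1.13	1.07
L	UUA	0.27	0.16	0.38	0.18	0.49
L	UUG	1.64	1.07	1.54	0.71	0.78
L	CUU	1.25	1.25	0.59	0.87	0.81
L	CUC	1.22	1.24	1.30	1.40	1.18
L	CUA	0.65	0.77	0.76	0.51	0.39
L	CUG	0.96	1.51	1.44	2.33	2.35
I	AUU	0.96	1.19	2.01	1.12	1.06
I	AUC	1.20	1.01	0.14	1.27	1.42
I	AUA	0.85	0.79	0.86	0.61	0.52
V	GUU	1.14	0.82	2.20	0.41	0.73
V	GUC	0.46	0.81	0.44	1.10	0.98
V	GUA	1.29	1.19	0.62	0.33	0.45
V	GUG	1.12	1.18	0.73	2.15	1.83
S	UCU	0.99	0.45	0.81	1.13	1.09
S	UCC	2.01	2.63	1.24	1.03	1.30
S	UCA	0.42	0.35	0.20	0.37	0.87
S	UCG	0.19	0.01	0.93	0.00	0.37
S	AGU	0.80	1.28	0.62	1.26	0.91
S	AGC	1.59	1.27	2.21	2.19	1.46
P	CCU	0.98	0.94	1.03	0.34	1.12
P	CCC	1.68	1.60	0.90	1.53	1.31
P	CCA	1.02	1.12	1.22	1.36	1.06
P	CCG	0.32	0.35	0.85	0.76	0.51
T	ACU	1.35	1.24	1.13	1.58	0.94
T	ACC	1.66	1.51	1.39	1.28	1.41
T	ACA	0.46	0.70	1.05	0.79	1.10
T	ACG	0.52	0.55	0.43	0.35	0.55
A	GCU	1.57	2.28	1.24	1.00	1.02
A	GCC	1.59	0.82	0.92	1.55	1.64
A	GCA	0.42	0.42	0.64	0.55	0.89
A	GCG	0.42	0.48	1.20	0.90	0.45
Y	UAU	1.05	0.93	1.22	1.12	0.87
Y	UAC	0.95	1.07	0.78	0.88	1.13
H	CAU	0.53	0.65	0.19	0.90	0.80
H	CAC	1.47	1.35	1.81	1.10	1.20
Q	CAA	0.73	0.84	1.34	0.93	0.50
Q	CAG	1.27	1.16	0.66	1.07	1.50
N	AAU	1.23	1.39	0.87	0.73	0.93
N	AAC	0.77	0.61	1.13	1.27	1.07
K	AAA	1.03	1.16	1.17	0.90	0.87
K	AAG	0.97	0.84	0.83	1.10	1.13
D	GAU	1.00	1.06	1.22	0.90	0.92
D	GAC	1.00	0.94	0.78	1.10	1.08
E	GAA	1.03	1.30	0.90	0.74	0.86
E	GAG	0.97	0.70	1.10	1.26	1.14
C	UGU	1.12	0.87	1.14	1.46	0.91
C	UGC	0.88	1.13	0.86	0.54	1.09
R	CGU	0.67	0.51	0.76	0.57	0.45
R	CGC	1.32	1.93	0.78	0.75	1.05
R	CGA	0.28	0.36	0.36	0.00	0.67
R	CGG	0.65	0.50	0.90	1.50	1.24
R	AGA	2.05	1.83	1.67	1.68	1.29
R	AGG	1.04	0.88	1.53	1.50	1.30
G	GGU	0.85	0.79	0.88	0.56	0.63
G	GGC	1.16	1.18	0.57	1.15	1.36
G	GGA	1.09	1.11	1.02	1.33	1.00
G	GGG	0.91	0.92	1.53	0.96	1.01
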