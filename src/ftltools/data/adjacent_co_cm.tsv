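interval	background	cm_without	se_without	cm_with	se_with	ratio_printed
1b	Col/Col	10.69	0.40	3.31	0.30	3.23
1b	Col/Ler	9.78	0.37	1.22	0.18	8.04
1c	Col/Col	20.61	0.45	7.92	0.76	2.60
1c	Col/Ler	22.13	0.46	3.52	0.50	6.29
2a	Col/Col	3.20	0.16	1.18	0.30	2.75
2a	Col/Ler	2.42	0.14	0.37	0.21	6.55
2b	Col/Col	4.65	0.19	1.74	0.44	2.68
2b	Col/Ler	3.41	0.16	0.53	0.30	6.44
3b	Col/Col	20.84	0.37	6.95	0.82	2.31
3b	Col/Ler	14.73	0.40	2.92	0.76	5.05
3c	Col/Col	7.65	0.30	1.90	0.22	4.03
3c	Col/Ler	4.28	0.30	0.66	0.18	6.46
5c	Col/Col	5.87	0.23	3.23	0.47	1.82
5c	Col/Ler	5.85	0.22	2.35	0.43	2.49
5d	Col/Col	5.85	0.23	3.22	0.48	1.82
5d	Col/Ler	5.29	0.22	2.07	0.38	2.56
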