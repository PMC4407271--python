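interval	background	PD	NPD	T	cm_printed	se_printed
1b	Col/Col	3976	3	742	8.05	0.29
1b	Col/Ler	4395	2	652	6.58	0.25
1c	Col/Col	3022	11	1695	18.62	0.04
1c	Col/Ler	3156	18	1891	19.73	0.04
2a	Col/Col	6787	2	430	3.06	0.15
2a	Col/Ler	5920	0	283	2.28	0.13
2b	Col/Col	6582	2	635	4.48	0.18
2b	Col/Ler	5796	0	407	3.28	0.16
3b	Col/Col	4363	22	2557	19.37	0.35
3b	Col/Ler	2758	2	1056	13.99	0.38
3c	Col/Col	6185	5	736	5.53	0.21
3c	Col/Ler	3576	2	238	3.28	0.22
5c	Col/Col	5356	1	666	5.58	0.21
5c	Col/Ler	5458	0	676	5.51	0.20
5d	Col/Col	5358	1	664	5.56	0.21
5d	Col/Ler	5540	2	594	4.94	0.20
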