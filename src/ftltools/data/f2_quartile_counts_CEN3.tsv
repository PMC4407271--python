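marker_bp	hot_het	hot_hom	cold_het	cold_hom	fdr_p_printed
259000	16	14	17	13	1
2718000	16	14	18	12	1
5352000	19	11	17	13	1
7674000	20	10	12	18	0.129
8495000	23	7	13	17	0.0389
9404000	26	4	16	14	0.0308
11115724	30	0	30	0	1
16520560	30	0	30	0	1
21008000	27	3	14	16	0.00477
22076000	23	7	12	18	0.0308
23040000	24	6	10	20	0.00477
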