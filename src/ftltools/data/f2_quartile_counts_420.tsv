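marker_bp	hot_het	hot_hom	cold_het	cold_hom	fdr_p_printed
259000	34	0	34	0	1
2718000	34	0	34	0	1
5352000	34	0	34	0	1
6375000	21	13	34	0	4.36e-04
6948000	17	17	33	1	1.05e-04
7674000	15	19	33	1	2.12e-05
8495000	12	22	34	0	3.65e-07
9404000	8	26	33	1	3.79e-08
10695000	8	26	30	4	1.36e-06
11649000	11	23	27	7	4.36e-04
12356000	11	23	27	7	4.36e-04
15949000	13	21	23	11	4.48e-02
19165000	17	17	21	13	0.591
23040000	13	21	17	17	0.591
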