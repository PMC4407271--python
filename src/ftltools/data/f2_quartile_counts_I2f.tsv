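marker_bp	hot_het	hot_hom	cold_het	cold_hom	fdr_p_printed
132000	9	11	8	12	NA
2346000	7	13	8	12	NA
4748000	8	12	9	11	NA
6789000	7	13	11	9	0.631
11443000	5	15	20	0	6.26e-05
13036000	7	13	20	0	3.32e-04
14117000	9	11	20	0	1.30e-03
15240000	9	11	20	0	1.30e-03
16909000	13	7	20	0	0.0262
17439000	16	4	20	0	0.238
18287000	20	0	20	0	1
18960000	20	0	20	0	1
19311000	18	2	20	0	0.764
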