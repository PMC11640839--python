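signature	GSE11318	GSE53786	GSE98588	TCGA-DLBC	NCICCR-DLBCL	GSE125966	internal_test
four_gene_pairs	6	2	1	3	3	5	2
pan_2021	8	9	3	1	8	2	3
xiong_2022	1	5	6	4	4	6	5
yan_2022	7	6	2	2	6	4	4
ma_2022	2	1	7	6	2	7	7
hou_2023	9	8	9	9	10	8	7
shi_2023	4	3	5	5	7	2	6
zhao_2023	5	7	10	7	9	10	10
ren_2023	3	4	4	8	1	1	1
wang_2024	10	10	8	10	5	9	9
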