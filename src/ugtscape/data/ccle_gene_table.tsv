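gene	n_cell_lines	translation_start_site	missense	nonsense	frame_shift_del	frame_shift_ins	in_frame_del	nonstop	splice_site	printed_sum	n_overlap_tcga
UGT1A8	28	0	20	2	8	4	0	0	0	34	5
UGT1A10	35	0	36	2	0	0	0	0	0	38	1
UGT1A9	31	0	28	0	4	6	0	0	0	39	4
UGT1A7	35	1	32	1	2	1	0	0	0	36	10
UGT1A6	16	0	12	1	2	1	0	0	0	16	3
UGT1A5	17	0	13	0	1	2	1	0	0	17	2
UGT1A4	30	0	21	0	7	2	0	0	1	31	2
UGT1A3	21	0	11	0	6	3	1	0	0	21	0
UGT1A1	14	0	15	0	0	0	0	0	0	15	1
1A E2-5	22	0	19	0	6	1	0	0	0	26	6
UGT2A1	15	0	13	0	2	0	0	0	0	15	0
UGT2A2	22	0	22	0	0	0	0	0	0	22	2
2A1/2A2 E2-6	30	0	13	3	0	0	0	0	3	19	1
UGT2A3	45	0	42	4	4	1	0	0	0	51	7
UGT2B4	50	0	49	6	3	1	0	0	0	59	10
UGT2B7	42	0	33	4	2	1	0	0	2	42	6
UGT2B10	60	0	49	5	4	1	0	0	3	62	11
UGT2B11	54	0	51	3	0	0	0	0	2	56	7
UGT2B15	46	0	45	3	0	1	0	0	0	49	8
UGT2B17	18	0	16	1	1	0	0	0	1	19	1
UGT2B28	66	0	64	7	2	1	0	0	2	76	10
UGT3A1	50	0	49	4	2	0	0	0	3	58	6
UGT3A2	55	1	47	3	6	1	0	2	0	60	7
UGT8	29	0	28	2	3	1	0	0	0	34	4
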