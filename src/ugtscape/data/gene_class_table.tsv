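gene	utr5	missense	missense_deleterious	translation_start_site	nonsense	silent	frame_shift_del	frame_shift_ins	in_frame_del	in_frame_ins	nonstop	intron	splice_site	utr3	printed_sum	refseq_transcript
UGT1A8	3	47	26	0	8	19	4	2	0	0	0	0	0	0	83	ENST00000373450
UGT1A10	3	59	31	0	3	24	4	0	0	0	0	0	1	0	94	ENST00000344644
UGT1A9	2	56	27	0	7	19	5	7	0	0	0	0	0	0	96	ENST00000354728
UGT1A7	0	46	25	0	3	12	4	3	0	0	0	0	0	0	68	ENST00000373426
UGT1A6	14	43	18	1	5	19	1	0	0	0	0	0	0	0	83	ENST00000305139
UGT1A5	0	48	18	0	2	24	1	1	0	0	0	0	0	0	76	ENST00000373414
UGT1A4	1	49	17	0	4	20	10	2	0	0	0	0	0	0	86	ENST00000373409
UGT1A3	1	47	18	0	2	24	4	1	0	0	0	0	0	0	79	ENST00000482026
UGT1A1	2	42	0	0	0	32	2	1	0	0	0	0	0	0	79	ENST00000609767
1A E2-5	0	43	29	0	1	25	7	0	2	0	0	0	1	8	87	ENST00000344644/ENST00000373409
UGT2A1	5	44	29	0	5	15	3	0	1	0	0	2	3	0	78	ENST00000514019
UGT2A2	0	49	15	0	7	15	2	0	0	0	0	0	0	0	73	ENST00000457664
2A1/2A2 E2-6	0	70	53	0	11	22	6	0	0	0	0	1	5	6	121	ENST00000514019/ENST00000503640
UGT2A3	2	127	84	0	10	33	7	3	0	0	0	0	3	11	196	ENST00000251566
UGT2B4	7	151	93	0	21	74	5	1	2	0	0	0	6	22	289	ENST00000305107
UGT2B7	2	106	65	0	4	37	4	0	0	0	0	1	3	15	172	ENST00000305231
UGT2B10	3	116	77	0	11	27	4	2	0	0	0	3	7	20	193	ENST00000265403
UGT2B11	20	115	79	0	16	38	3	0	0	0	0	1	4	8	205	ENST00000446444
UGT2B15	2	122	78	0	14	38	3	1	0	0	1	1	1	27	210	ENST00000338206
UGT2B17	1	100	61	0	10	29	5	2	0	0	0	0	0	0	147	ENST00000317746
UGT2B28	1	133	80	0	15	47	1	0	0	0	0	0	4	9	210	ENST00000335568
UGT3A1	20	153	64	0	9	68	2	1	0	0	0	19	6	29	307	ENST00000274278
UGT3A2	10	143	65	0	12	64	3	1	0	0	0	0	1	21	255	ENST00000282507
UGT8	0	89	47	0	4	29	3	1	0	0	0	8	0	6	140	ENST00000310836
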