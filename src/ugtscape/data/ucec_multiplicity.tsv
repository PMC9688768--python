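n_mutations	n_tumors
1	71
2	21
3	12
4	3
5	3
6	2
7	2
8	2
10	2
13	1
14	2
18	1
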