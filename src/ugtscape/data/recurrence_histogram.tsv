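occurrences	n_groups
2	163
3	31
4	11
5	6
6	3
8	1
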