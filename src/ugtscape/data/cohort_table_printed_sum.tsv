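field	printed_value
n_tumors	10069
total_mutations	2686092
mutations_per_tumor	266
n_tumors_with_ugt	1802
total_ugt_mutations	3427
n_missense_frameshift_nonsense	2260
fraction_with_ugt	0.178
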