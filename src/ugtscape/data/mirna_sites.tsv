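gene	mirna	site_start	site_end	seed_start	seed_end
1A E2-5	miR-200a-3p	55	75	69	75
1A E2-5	miR-141-3p	58	75	69	75
UGT2B4	miR-216b-5p	64	84	78	84
UGT2B7	miR-376c-3p	20	46	40	46
UGT2B15	miR-331-3p	30	56	50	56
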