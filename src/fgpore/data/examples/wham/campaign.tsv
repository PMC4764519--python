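file	center	bias_stiffness	lateral_stiffness	n_steps	equilibration_steps	seed
window_000.tsv	-2.0	39.909600000000005	100.0	0	0	7
window_001.tsv	-1.5	39.909600000000005	100.0	0	0	8
window_002.tsv	-1.0	39.909600000000005	100.0	0	0	9
window_003.tsv	-0.5	39.909600000000005	100.0	0	0	10
window_004.tsv	0.0	39.909600000000005	100.0	0	0	11
window_005.tsv	0.5	39.909600000000005	100.0	0	0	12
window_006.tsv	1.0	39.909600000000005	100.0	0	0	13
window_007.tsv	1.5	39.909600000000005	100.0	0	0	14
window_008.tsv	2.0	39.909600000000005	100.0	0	0	15
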