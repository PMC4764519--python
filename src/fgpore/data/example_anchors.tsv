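# Example anchor table for a full-scale pore (L = 60 nm).
# Ring placements and sequences are plausible synthetic stand-ins,
# NOT canonical yeast coordinates or sequences; replace with real
# data for production use.
nup_name	ring_z	ring_radius	copies	sequence_id
Nsp1	6.0	31.14	32	nsp1
Nup49	-2.0	30.13	16	nup49
Nup57	2.0	30.13	16	nup57
Nup42	14.0	36.20	8	nup42
Nup159	15.4	37.50	8	nup159
Nup1	-15.4	37.50	8	nup1
Nup60	-14.0	36.20	8	nup60
Nup100	10.0	33.16	8	nup100
Nup116	12.0	34.55	8	nup116
Nup145	-10.0	33.16	8	nup145
Nup2	-12.0	34.55	8	nup2
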