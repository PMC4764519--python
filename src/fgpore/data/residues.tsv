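# Per-residue coarse-grained parameters (one bead per amino acid).
# hydrophobicity: dimensionless, min-max normalised to [0, 1] with F (Phe) = 1.0
#   by construction; values are an editable composite hydropathy ranking, not a
#   calibrated scale. charge: elementary charges at neutral pH. radius: nm.
# 'X' is the pseudo-residue used for cargo-surface binding spots (F-like).
code	hydrophobicity	charge	radius
A	0.70	0	0.3
R	0.26	1	0.3
N	0.30	0	0.3
D	0.17	-1	0.3
C	0.75	0	0.3
Q	0.30	0	0.3
E	0.18	-1	0.3
G	0.52	0	0.3
H	0.45	0	0.3
I	0.94	0	0.3
L	0.94	0	0.3
K	0.24	1	0.3
M	0.85	0	0.3
F	1.00	0	0.3
P	0.39	0	0.3
S	0.40	0	0.3
T	0.43	0	0.3
W	0.91	0	0.3
Y	0.72	0	0.3
V	0.85	0	0.3
X	1.00	0	0.3
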