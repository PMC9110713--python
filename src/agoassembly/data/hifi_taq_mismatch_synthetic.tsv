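# Synthetic stand-in mismatch pairing profile for a thermostable high-fidelity
# ligase: Watson-Crick = 1.0, G.T wobble = 0.3, all other mismatches = 0.05.
# Replace with a measured profile (same 16-row format) for production use.
base_a	base_b	weight
A	A	0.05
A	C	0.05
A	G	0.05
A	T	1.0
C	A	0.05
C	C	0.05
C	G	1.0
C	T	0.05
G	A	0.05
G	C	1.0
G	G	0.05
G	T	0.3
T	A	1.0
T	C	0.05
T	G	0.3
T	T	0.05
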