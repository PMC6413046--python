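# name: V-scale
# k: 3
# source: reconstructed: normalized vdW side-chain volume, net charge index, Fauchere-Pliska pi
# provenance: transcribed
aa	p1	p2	p3
A	1	0.007187	0.31
C	2.43	-0.03661	1.54
D	2.78	-0.02382	-0.77
E	3.78	0.006802	-0.64
F	5.89	0.037552	1.79
G	0	0.179052	0
H	4.66	-0.01069	0.13
I	4	0.021631	1.8
K	4.77	0.017708	-0.99
L	4	0.051672	1.7
M	4.43	0.002683	1.23
N	2.95	0.005392	-0.6
P	2.72	0.239531	0.72
Q	3.95	0.049211	-0.22
R	6.13	0.043587	-1.01
S	1.6	0.004627	-0.04
T	2.6	0.003352	0.26
V	3	0.057004	1.22
W	8.08	0.037977	2.25
Y	6.47	0.023599	0.96
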