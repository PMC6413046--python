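# name: FASGAI
# k: 6
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6
A	0.3215	-0.9781	1.5656	0.6385	-0.6193	-1.7219
C	0.3173	-0.3522	0.1806	-1.5037	2.0675	-0.8389
D	-1.3587	0.0535	0.8125	-1.5566	-0.7623	0.9464
E	-0.8958	0.5343	1.7395	-0.2075	-1.9111	1.3406
F	1.5835	0.2174	-0.2514	-0.2057	-0.7764	-0.0708
G	-0.8766	-2.1545	-1.2631	0.2576	-0.4291	-0.3757
H	-0.1375	1.153	-0.0852	-0.3114	-0.3167	-2.1848
I	1.2639	-0.6102	0.3029	0.7779	0.7476	1.6985
K	-0.8547	0.9465	0.1836	1.6447	-0.0464	-0.9636
L	1.2582	-0.5724	0.4012	0.6925	-0.0192	0.2947
M	0.9223	0.2625	1.3761	0.0087	-0.1108	-0.749
N	-1.1473	0.0357	-0.266	-0.9989	0.5068	-0.1546
P	-0.5767	-1.6302	-1.9479	0.5611	-1.3301	-0.0471
Q	-0.601	0.4086	0.2441	0.2369	-0.1511	1.2285
R	-1.1021	1.7228	-0.7817	2.3054	1.1224	0.341
S	-0.9483	-0.5311	0.056	-0.7278	0.9086	-0.3307
T	-0.301	-0.1115	0.2924	-0.4057	1.2025	0.2249
V	1.1697	-0.8527	0.3374	0.7479	0.7385	0.6751
W	1.5206	1.464	-1.6086	-0.8706	-1.4558	-0.2705
Y	0.4426	0.9946	-1.2879	-1.0835	0.6344	0.9577
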