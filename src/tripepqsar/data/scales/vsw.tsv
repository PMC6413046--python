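# name: VSW
# k: 9
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9
A	-1.5564	-0.8752	-0.6598	-0.7471	0.1735	-1.0284	-0.1057	-0.9272	0.0497
C	-1.0044	-0.4605	-0.0612	-0.2051	1.2693	1.5798	3.0969	-0.4119	0.1288
D	-0.5555	-0.4553	-0.6509	-0.5618	0.8545	0.6318	-1.7996	-0.118	0.6376
E	0.3344	1.614	-0.8615	-0.0296	-1.8632	2.3438	-0.4139	-1.5409	-0.0775
F	0.7609	0.3134	0.0573	1.5614	0.9293	-0.1636	-0.3111	-0.1474	-1.074
G	-1.9474	0.5699	3.4094	0.1168	-0.7692	-0.1707	-0.3994	-0.3668	-0.8085
H	0.2657	0.2853	-0.1098	0.9356	0.7225	0.2115	-0.2603	0.6981	-1.6769
I	0.2115	0.0611	-0.5279	0.4398	-0.9079	-0.7413	0.369	1.5661	0.1901
K	1.0384	0.5501	0.6934	-0.1982	-0.7281	0.6111	0.6631	1.2525	0.8944
L	0.4779	1.3602	0.1847	0.2266	0.1919	-1.5709	1.4189	0.252	0.2862
M	0.5626	-0.9282	-0.2296	-2.0572	0.0315	0.5402	-0.1428	1.7199	-2.2872
N	-0.3074	0.8024	-0.0186	0.5006	2.5235	0.0385	-1.2752	0.1119	0.7335
P	-0.5882	1.0153	-1.5237	-0.9846	-0.6216	-2.0444	0.361	-1.1591	-0.9402
Q	0.3534	0.1505	0.1596	-0.2424	0.318	0.5317	-0.0044	0.5624	0.4655
R	1.6808	0.5418	0.7274	-1.4924	0.8952	-0.3417	0.1025	-1.1617	1.2653
S	-1.2675	-1.6318	-0.428	-0.325	-0.4903	0.4235	-0.0781	0.3045	1.1537
T	-0.5472	0.7648	-0.7191	0.5759	-0.4387	0.5038	-0.7587	0.1747	-0.3122
V	-0.531	-0.3641	-0.6173	1.74	-0.9137	-0.5307	0.0759	1.1099	1.3404
W	1.432	-2.2994	0.2268	1.5962	-0.2961	-0.1514	0.2579	-1.8752	-0.8013
Y	1.1871	-1.0144	0.9489	-0.8493	-0.8804	-0.6726	-0.796	-0.0437	0.8323
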