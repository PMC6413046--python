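# name: DPPS
# k: 10
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10
A	-1.3138	-0.6963	-0.2554	0.2593	-0.4429	-0.2184	-0.7629	0.4377	-0.7281	-0.2858
C	-0.9001	-0.2785	-0.2354	-0.0642	2.226	0.1501	1.4011	-0.5016	-0.2725	-1.5211
D	-0.4534	1.186	-0.6741	-0.3366	-0.8201	1.2122	0.6791	0.0143	-0.9249	1.7914
E	0.0319	1.0837	-0.2233	-0.0639	-1.0051	0.3424	1.4429	0.206	0.3421	1.7903
F	1.0571	-1.2088	-0.0239	-0.6353	-0.7545	0.5343	0.138	-0.5089	-1.6751	-0.3271
G	-1.828	-0.824	-0.2642	-1.106	-0.4407	-2.6171	0.2232	0.0852	-1.324	0.5473
H	0.4526	0.2341	-1.5679	-1.242	1.1546	-0.687	-1.2027	-2.079	1.8039	1.2424
I	0.0536	-0.8808	1.1486	0.4058	-1.0387	0.5864	-0.232	-0.8868	0.8164	-0.3862
K	0.4542	0.367	1.3617	0.5027	0.306	-0.1939	-0.459	1.3406	0.129	0.7976
L	0.0689	-0.7626	1.523	0.4323	-0.755	0.2486	-0.3916	-1.0709	-0.101	0.3142
M	0.116	-0.5024	0.8098	0.9443	2.071	0.4083	2.0189	-0.2698	-0.1315	0.8862
N	-0.4148	1.2518	-0.4969	-0.6636	-0.7456	-0.1153	0.6556	-0.0048	0.6822	-1.851
P	-0.3365	-1.3654	0.1008	-0.1272	0.2321	-0.3973	-0.2915	2.5265	2.1721	0.4686
Q	0.0845	1.2976	0.032	-0.2074	-1.1251	-0.2527	1.1943	0.2926	1.1148	-1.4924
R	1.0569	2.1417	1.8383	-0.0127	0.8909	-1.581	-1.241	-0.0497	-0.7957	-0.2295
S	-1.0545	0.5304	-0.649	0.0181	0.6089	1.3919	-1.3476	0.5504	-0.8148	-0.3729
T	-0.6232	0.4687	-0.5128	0.465	0.5495	1.6152	-1.5805	0.4245	-0.1184	-0.2677
V	-0.4385	-0.7876	0.6286	0.7734	-0.7389	0.2187	-0.3083	-1.5598	0.8182	-0.3372
W	2.3909	-1.0191	-0.3332	-2.1825	0.1732	0.5689	0.103	0.8264	-0.5122	-0.4991
Y	1.5961	-0.2357	-2.2068	2.8405	-0.3454	-1.2142	-0.0389	0.2273	-0.4806	-0.2679
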