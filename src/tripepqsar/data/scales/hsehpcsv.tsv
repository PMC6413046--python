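# name: HSEHPCSV
# k: 12
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12
A	-1.4594	-0.7214	-0.3731	-0.0089	-0.6785	-0.0259	0.0289	0.1091	-0.2572	-0.7379	0.1527	0.4666
C	-0.895	-0.358	0.3393	0.5021	1.8388	1.1304	-1.7116	0.0894	-0.2285	-0.0701	-1.5782	-0.5603
D	-0.0399	1.6044	-1.0601	-0.3165	0.4987	0.7621	1.0155	-1.3562	-0.7024	-0.5927	-0.1951	0.1806
E	0.3521	1.552	-0.646	-0.5935	0.5668	1.0195	1.1555	-1.3695	-0.5105	-0.9405	0.3584	-0.1551
F	0.5389	-1.3627	-0.4513	-0.912	-0.5443	0.2861	-0.0947	0.1064	-0.3326	-0.4955	-0.8301	3.5081
G	-2.1605	-0.5371	-1.1188	0.6025	-0.9509	-0.5034	-0.6385	0.488	-1.445	-1.1841	1.0518	-0.8692
H	0.7032	-0.3983	-1.2449	2.6842	-0.4957	0.2858	-0.1365	-0.7969	2.6956	-0.533	0.2036	0.0913
I	-0.2451	-0.6792	1.0533	-0.8755	-0.8178	0.4572	0.5438	-0.6627	0.7241	0.2666	-0.2962	-0.7721
K	0.3624	0.1379	1.5042	-0.117	-0.2857	-0.3763	0.1224	0.1191	0.1698	-0.0768	3.0582	0.4972
L	-0.2451	-0.6792	1.0533	-0.8755	-0.8178	0.4572	0.5438	-0.6627	0.7241	0.2666	-0.2962	-0.7721
M	-0.0162	-0.6056	1.2112	0.1619	2.2864	1.2965	-0.7979	0.1332	0.121	0.0751	1.2183	0.3932
N	0.02	1.4861	-0.2986	-0.1603	-0.7584	0.7282	-0.2967	2.2228	0.5091	0.4003	-0.6145	0.0186
P	0.0685	-0.4384	0.8558	1.0464	1.4008	-1.6325	2.7195	1.4891	-0.1894	-0.8885	-0.9413	-0.1218
Q	0.392	1.4926	0.1361	-0.3252	-0.731	0.7907	-0.2523	2.0437	0.4784	0.2252	0.0979	-0.0335
R	1.2182	1.2261	1.8259	0.9904	-0.9454	-1.5329	-1.6733	-1.0415	-1.1276	-0.8665	-1.0117	0.1076
S	-0.8935	0.5054	-0.6318	0.5018	0.4532	-1.067	-0.245	-0.2829	-0.2906	1.6978	0.2807	0.6877
T	-0.5931	0.4856	-0.38	-0.0571	0.3476	-1.2553	0.1889	-0.6884	0.1803	2.8338	-0.1124	0.363
V	-0.6874	-0.6896	0.6515	-0.77	-0.9121	0.1996	0.3877	-0.5532	0.5494	0.2541	-0.9915	-0.8375
W	2.3218	-1.5654	-0.9247	0.7062	-0.5092	0.9041	0.2993	0.3453	-2.081	1.2632	0.2185	-1.167
Y	1.2582	-0.4551	-1.5012	-2.1837	1.0546	-1.924	-1.1586	0.2679	1.0129	-0.8973	0.2269	-1.0253
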