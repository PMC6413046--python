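# name: HESH
# k: 12
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12
A	-1.2225	-0.7462	-0.1028	-0.4795	-0.0264	-0.4788	-0.7097	0.4646	-0.256	0.0023	-0.0019	0.5302
C	-0.8856	-0.6114	0.7961	0.4134	1.7239	-0.0952	1.803	-0.2581	0.3451	-0.4408	-2.0633	0.0867
D	-0.4709	1.4995	-0.0752	-1.2813	-0.723	0.5804	1.2075	-0.187	-1.0791	1.2871	0.1427	-0.2788
E	-0.064	1.3926	-0.2398	-0.7717	-0.6011	0.2818	0.9485	-0.9967	-0.8257	1.6983	-0.1302	0.3959
F	1.0657	-0.7756	-0.708	-0.5032	-0.3139	-1.0743	0.2259	0.3827	-0.5854	-0.279	0.3349	-3.5389
G	-1.7412	-1.0067	0.958	-0.8185	0.7209	-1.8276	-1.5244	-0.7441	-1.2021	0.574	0.4359	0.2262
H	0.8244	-0.2957	2.6268	-0.5667	-0.1438	0.9675	-0.9202	0.6941	2.1496	1.649	0.288	-0.5313
I	0.0252	-0.524	-1.107	0.8185	-1.0822	-0.2794	0.0288	0.5258	0.771	0.6014	-0.932	0.2897
K	0.2611	0.3237	-0.4441	1.4468	0.0072	-0.2737	-0.4322	0.2253	-0.1375	0.13	2.6591	1.0447
L	-0.0385	-0.4885	-1.071	0.9324	-0.841	-0.5859	-0.1605	0.6553	0.3646	0.8102	-0.3113	0.1203
M	-0.0354	-0.6934	0.1025	1.3943	1.6049	0.1091	2.1053	-0.3426	0.3817	0.4949	1.606	-0.2714
N	-0.3883	1.4381	0.3049	-0.4154	-0.3786	-0.8969	-0.0329	-0.7351	1.3897	-1.6741	0.032	-0.3707
P	-0.2159	-1.7511	-0.0183	0.325	-1.3805	2.2967	-0.4144	-2.5198	-0.333	-0.9359	0.0859	-0.2007
Q	0.0075	1.4789	0.0103	0.0392	-0.3847	-1.0359	-0.0652	-1.1448	1.4348	-1.2918	0.2259	0.2039
R	0.7571	1.6312	0.7252	2.3386	0.8187	0.4963	-1.6428	-0.0803	-1.5793	0.0486	-1.321	-0.6434
S	-1.0209	0.1951	0.3328	-0.588	0.3042	1.0232	-0.0818	1.5832	-0.6646	-1.235	0.4518	-0.162
T	-0.6363	0.3167	-0.3275	-0.3815	-0.2151	1.4732	0.1461	2.0365	-0.1763	-1.2335	0.2113	0.1989
V	-0.3857	-0.4765	-1.0469	0.3696	-0.7156	-0.3863	-0.2054	0.5678	0.7962	0.6675	-1.234	0.5766
W	2.6015	-0.8542	1.2551	-0.5962	-0.8009	-1.0412	0.8713	0.4067	-1.3058	-1.0002	-0.3208	1.7207
Y	1.5628	-0.0527	-1.971	-1.6759	2.427	0.7471	-1.1469	-0.5337	0.512	0.1271	-0.159	0.6032
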