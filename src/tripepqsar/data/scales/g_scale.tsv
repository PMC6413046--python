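# name: G-scale
# k: 8
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3	p4	p5	p6	p7	p8
A	-1.1726	-0.7779	-0.1068	-0.3248	0.0654	-0.0961	-0.7389	0.6374
C	-0.829	-0.7287	-0.2609	0.6119	2.2561	-0.0447	0.9609	-0.8581
D	-0.5703	1.5379	-0.6156	-1.2022	-0.2891	-0.8587	1.1106	-0.4636
E	-0.137	1.432	-0.1464	-0.856	-0.3881	-0.7702	0.7714	-1.0981
F	1.1185	-0.8275	0.2953	-0.8489	0.1198	-0.6814	-0.7262	-0.0779
G	-1.7622	-0.9367	-1.3416	0.0937	0.2091	0.7043	-2.4602	-0.7804
H	0.7984	-0.0283	-2.3371	1.2127	0.0284	-0.0906	0.2701	1.7948
I	0.1032	-0.6993	1.4783	-0.081	-0.6446	-0.844	-0.1204	0.5929
K	0.2533	0.439	1.0683	1.0391	-0.3374	0.3929	-0.3606	0.0047
L	0.0453	-0.6788	1.4956	0.0605	-0.4402	-0.7632	-0.425	0.5372
M	0.0517	-0.7699	0.8184	1.0237	1.9679	-0.163	1.4312	-1.1942
N	-0.4611	1.4058	-0.374	-0.2291	-0.0119	-0.4542	-0.8463	-0.5522
P	-0.2519	-1.5295	-0.5899	0.4285	-2.8301	1.1634	1.5357	-1.6113
Q	-0.0362	1.4083	0.2097	-0.0421	-0.1323	-0.498	-0.9632	-0.931
R	0.6997	1.6783	0.7992	2.4013	-0.2445	1.5911	-0.4818	0.2035
S	-1.0549	0.2098	-0.6052	-0.2372	0.2081	0.4577	0.7376	1.4342
T	-0.6322	0.2492	0.1085	-0.5007	-0.117	0.1232	1.2498	1.9987
V	-0.3061	-0.6817	1.2058	-0.3606	-0.3479	-0.6043	-0.3916	0.7328
W	2.6028	-0.6805	-1.3657	0.1642	0.0638	-1.4332	-0.3965	-0.3691
Y	1.5405	-0.0216	0.2642	-2.3529	0.8647	2.8689	-0.1566	-0.0002
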