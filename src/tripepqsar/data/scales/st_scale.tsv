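# name: ST-scale
# k: 8
# source: Yang L et al. (2010) Amino Acids 38:805
# provenance: transcribed
aa	p1	p2	p3	p4	p5	p6	p7	p8
A	-1.552	-0.791	-0.627	0.237	-0.461	-2.229	0.283	1.221
C	-0.139	0.523	-0.944	-0.498	-0.629	-0.39	-0.059	-0.835
D	-0.907	-0.054	-0.781	-0.248	1.12	0.101	-0.245	-0.075
E	-0.911	0.135	-0.232	-0.447	1.354	0.086	0.225	0.547
F	-0.019	0.024	1.08	-0.22	-0.937	0.57	-0.357	0.278
G	-1.844	-0.018	-0.184	0.573	-0.728	-3.317	0.166	2.522
H	-0.223	0.34	0.097	-0.258	0.276	-0.514	1.546	-0.725
I	-0.785	-1.01	-0.349	-0.097	-0.402	1.091	-0.139	-0.764
K	-0.478	0.595	-0.88	0.21	0.334	0.091	0.195	0.367
L	-0.826	-0.379	0.038	-0.059	-0.625	1.025	-0.229	-0.129
M	-0.693	0.498	0.658	0.457	-0.231	1.064	0.248	-0.778
N	-0.888	-0.057	-0.651	-0.214	0.917	0.164	-0.14	-0.166
P	-1.049	-0.407	-0.067	-0.066	-0.813	-0.89	0.021	-0.894
Q	-0.387	0.228	-0.029	-0.278	0.588	0.714	-0.102	-0.226
R	-0.059	0.731	-0.013	-0.096	-0.253	0.3	1.256	0.854
S	-1.343	-0.311	-0.917	-0.049	0.549	-1.533	0.166	0.28
T	-1.061	-0.928	-0.911	-0.063	0.538	-0.775	-0.147	-0.717
V	-1.133	-0.893	-0.325	0.303	-0.561	-0.175	-0.02	-0.311
W	0.853	0.039	0.26	-1.163	0.16	-0.202	1.01	0.195
Y	0.308	0.569	1.1	-0.464	-0.144	-0.354	-1.099	0.162
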