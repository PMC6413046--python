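# name: ISA-ECI
# k: 2
# source: Collantes ER, Dunn WJ (1995) J Med Chem 38:2705
# provenance: transcribed
aa	p1	p2
A	62.9	0.05
C	78.51	0.15
D	18.46	1.25
E	30.19	1.31
F	189.42	0.14
G	19.93	0.02
H	87.38	0.56
I	149.77	0.09
K	102.78	0.53
L	154.35	0.1
M	132.22	0.34
N	17.87	1.31
P	122.35	0.16
Q	19.53	1.36
R	52.98	1.69
S	19.75	0.56
T	59.44	0.65
V	120.91	0.07
W	179.16	1.08
Y	132.16	0.72
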