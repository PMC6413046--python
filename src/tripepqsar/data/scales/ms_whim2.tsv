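# name: MS-WHIM2
# k: 3
# source: synthetic stand-in: PCA of RDKit descriptors of the 20 amino acids (original published table unavailable)
# provenance: synthetic
aa	p1	p2	p3
A	-1.5335	-0.8978	-0.5659
C	-1.0039	-0.5449	-0.0872
D	-0.5503	-0.3608	-0.6592
E	0.3362	1.6024	-0.9682
F	0.7449	0.2641	0.0358
G	-1.9651	0.7358	3.3972
H	0.245	0.27	-0.0892
I	0.1973	-0.0034	-0.5032
K	1.0274	0.5733	0.6372
L	0.4575	1.2903	0.1003
M	0.5374	-0.9357	-0.17
N	-0.3072	0.8799	-0.0686
P	-0.5832	0.8798	-1.5107
Q	0.3604	0.2419	0.1537
R	1.704	0.6992	0.7408
S	-1.2503	-1.6217	-0.3889
T	-0.5436	0.6741	-0.8196
V	-0.5291	-0.4278	-0.5693
W	1.4319	-2.2823	0.3901
Y	1.2241	-1.0364	0.945
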