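no	sequence	activity
1	LTC	2.83
2	CQC	2.53
3	GTW	2.52
4	LFC	2.07
5	CLV	2.06
6	QKW	2.03
7	CME	1.99
8	YLL	1.91
9	QCL	1.69
10	LAC	1.69
11	GEC	1.64
12	EQC	1.52
13	FCM	1.51
14	CHI	1.45
15	ACQ	1.38
16	EEL	1.33
17	WEN	1.31
18	VYV	1.19
19	MHI	1.16
20	CAQ	1.12
21	WYS	1.12
22	KYL	1.08
23	CGA	1.08
24	KKY	1.08
25	NEN	1.08
26	ECA	1.07
27	DYK	1.06
28	KCL	1.05
29	YVE	1.05
30	LPM	1.04
31	TDY	1.01
32	QCH	1.00
33	TWY	0.96
34	RVY	0.95
35	KWE	0.90
36	CLL	0.89
37	LAM	0.85
38	YSL	0.81
39	MKG	0.80
40	QTM	0.80
41	LAL	0.76
42	QAL	0.73
43	MEN	0.73
44	MKC	0.72
45	LSF	0.69
46	TCG	0.67
47	SLA	0.65
48	TMK	0.64
49	LDT	0.62
50	EKF	0.54
51	VLV	0.53
52	MAA	0.44
53	PTQ	0.44
54	VAG	0.41
55	ALP	0.37
56	AVF	0.36
57	KVA	0.31
58	TQT	0.26
59	YKK	0.25
60	AQA	0.22
61	LRV	0.20
62	PTP	0.18
63	ALN	0.18
64	LEI	0.16
65	LVR	0.13
66	HIR	0.12
67	KKI	0.11
68	SFN	0.07
69	SLL	0.06
70	PAV	0.04
71	RLS	0.04
72	AGT	0.04
73	LLF	0.02
74	PMH	0.00
75	EEQ	-0.01
76	LVL	-0.02
77	QLE	-0.05
78	FDK	-0.07
79	LLL	-0.08
80	SAP	-0.08
81	LLQ	-0.12
82	NPT	-0.17
83	FNP	-0.20
84	LNE	-0.24
85	SAE	-0.26
86	KPT	-0.28
87	DIQ	-0.30
88	NGE	-0.30
89	QSA	-0.33
90	DAQ	-0.34
91	ENS	-0.34
92	ENG	-0.37
93	NSA	-0.37
94	EKT	-0.38
95	EQS	-0.38
96	AMA	-0.41
97	KID	-0.41
98	GAQ	-0.43
99	PLR	-0.44
100	ILL	-0.46
101	VRT	-0.46
102	IAE	-0.49
103	QSL	-0.49
104	KTK	-0.51
105	ASD	-0.52
106	APL	-0.52
107	AQS	-0.57
108	ENK	-0.57
109	TPE	-0.59
110	RTP	-0.59
111	VLD	-0.62
112	IRL	-0.62
113	AAS	-0.64
114	LQK	-0.64
115	FKI	-0.64
116	ISL	-0.66
117	ELK	-0.66
118	PEQ	-0.66
119	IDA	-0.68
120	LLA	-0.70
121	ALA	-0.72
122	GLD	-0.72
123	DIS	-0.72
124	PEG	-0.72
125	LDI	-0.74
126	AEP	-0.74
127	ALI	-0.77
128	LDA	-0.77
129	VFK	-0.77
130	ALK	-0.77
131	AQK	-0.82
132	IIA	-0.82
133	LIV	-0.85
134	EGD	-0.85
135	QKK	-0.85
136	IPA	-0.85
137	SDI	-0.89
138	VEE	-0.89
139	DDE	-0.89
140	KVL	-0.92
141	KFD	-0.92
142	IVT	-0.96
143	VTQ	-0.96
144	AEK	-0.96
145	TKI	-1.10
146	KIP	-1.15
147	LLD	-1.22
148	DLE	-1.22
149	PEV	-1.22
150	LKP	-1.40
151	ALE	-1.52
152	TQL	-1.52
153	LEE	-1.52
154	LEK	-1.70
155	DAL	-2.00
156	EVD	-2.00
157	VDD	-2.00
158	DEA	-2.00
159	ALT	
160	KGL	
161	IQK	
162	QKV	
163	GDL	
164	EIL	
165	KII	
166	NKV	
167	DTD	
168	EPE	
169	EAL	
170	DKA	
171	KAL	
172	LKA	
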