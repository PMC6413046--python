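no	sequence	activity
1	LHA	3.918
2	LHD	3.593
3	LHE	6.136
4	LHF	3.628
5	LHG	6.697
6	LHH	4.836
7	LHI	6.531
8	LHK	4.225
9	LHL	5.920
10	LHM	4.504
11	LHN	5.148
12	LHQ	4.136
13	LHR	5.184
14	LHS	4.293
15	LHT	5.584
16	LHV	3.481
17	LHW	6.791
18	LHY	4.203
19	LWA	1.192
20	LWD	1.717
21	LWE	1.717
22	LWF	1.414
23	LWG	1.313
24	LWH	3.212
25	LWI	1.111
26	LWK	1.899
27	LWL	0.6060
28	LWM	1.394
29	LWN	1.313
30	LWQ	2.505
31	LWR	2.909
32	LWS	2.020
33	LWT	2.020
34	LWV	1.616
35	LWW	3.515
36	LWY	2.222
37	PHA	5.793
38	PHD	4.622
39	PHE	6.152
40	PHF	3.916
41	PHG	5.197
42	PHH	6.051
43	PHI	4.916
44	PHK	3.426
45	PHL	5.311
46	PHM	3.714
47	PHN	6.061
48	PHQ	3.718
49	PHR	4.751
50	PHS	4.042
51	PHT	6.247
52	PHV	3.335
53	PHW	6.535
54	PHY	4.227
55	PWA	1.396
56	PWD	1.096
57	PWE	1.096
58	PWF	0.9192
59	PWG	2.687
60	PWH	1.184
61	PWI	1.396
62	PWK	0.4066
63	PWL	1.096
64	PWM	0.7955
65	PWN	2.104
66	PWQ	1.202
67	PWR	2.705
68	PWS	1.096
69	PWT	2.598
70	PWV	1.008
71	PWW	2.899
72	PWY	1.114
73	RHA	5.205
74	RHD	3.304
75	RHE	5.096
76	RHF	3.300
77	RHG	5.725
78	RHH	3.296
79	RHI	4.806
80	RHK	2.694
81	RHL	3.501
82	RHM	3.218
83	RHN	5.713
84	RHQ	3.108
85	RHR	4.302
86	RHS	3.386
87	RHT	5.987
88	RHV	3.206
89	RHW	5.878
90	RHY	3.378
91	RWA	1.212
92	RWD	0.9091
93	RWE	1.091
94	RWF	0.9091
95	RWG	1.717
96	RWH	1.091
97	RWI	1.232
98	RWK	0.6061
99	RWL	3.212
100	RWM	0.7273
101	RWN	2.404
102	RWQ	0.6061
103	RWR	2.384
104	RWS	0.8081
105	RWT	3.818
106	RWV	0.6061
107	RWW	2.707
108	RWY	0.8081
109	DHH	0.9045
110	EHH	0.9045
111	HHH	0.0000
112	KHH	0.0000
113	AHH	2.020
114	IHH	2.020
115	FHH	1.803
116	WHH	1.803
117	YHH	1.803
118	GHH	1.089
119	NHH	1.089
120	QHH	1.089
121	MHH	2.015
122	SHH	1.320
123	THH	1.320
124	CHH	0.9369
125	HDH	1.477
126	HEH	1.477
127	HHH	0.0441
128	HKH	0.0441
129	HRH	0.0441
130	HAH	0.9518
131	HIH	0.9518
132	HLH	0.9518
133	HFH	2.026
134	HWH	2.026
135	HYH	2.026
136	HGH	0.8318
137	HNH	0.8318
138	HQH	0.8318
139	HMH	0.8734
140	HSH	0.7304
141	HTH	0.7304
142	HCH	0.9747
143	HHD	0.1877
144	HHE	0.1877
145	HHH	0.0635
146	HHK	0.0635
147	HHR	0.0635
148	HHA	0.0680
149	HHI	0.0680
150	HHL	0.0680
151	HHF	3.612
152	HHW	3.612
153	HHY	3.612
154	HHG	0.3170
155	HHN	0.3170
156	HHQ	0.3170
157	HHM	0.0817
158	HHS	0.0862
159	HHT	0.0862
160	HHC	0.1277
161	DYY	3.417
162	EYY	3.417
163	HYY	2.257
164	KYY	2.257
165	RYY	2.257
166	AYY	3.071
167	IYY	3.071
168	LYY	3.071
169	FYY	1.911
170	WYY	1.911
171	YYY	1.911
172	GYY	5.071
173	NYY	5.071
174	QYY	5.071
175	MYY	1.991
176	SYY	3.070
177	TYY	3.070
178	CYY	0.4699
179	YDY	3.047
180	YEY	3.047
181	YHY	9.886
182	YKY	9.886
183	YRY	9.886
184	YAY	3.607
185	YIY	3.607
186	YLY	3.607
187	YFY	2.233
188	YWY	2.233
189	YYY	2.233
190	YGY	3.366
191	YNY	3.366
192	YQY	3.366
193	YMY	1.780
194	YSY	3.447
195	YTY	3.447
196	YCY	3.087
197	YYD	4.116
198	YYE	4.116
199	YYH	5.303
200	YYK	5.303
201	YYR	5.303
202	YYA	3.344
203	YYI	3.344
204	YYL	3.344
205	YYF	4.050
206	YYW	4.050
207	YYY	4.050
208	YYG	2.996
209	YYN	2.996
210	YYQ	2.996
211	YYM	2.103
212	YYS	3.983
213	YYT	3.983
214	YYC	0.6369
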