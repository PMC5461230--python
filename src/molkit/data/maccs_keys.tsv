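# MACCS-like 166 structural keys in the restricted predicate language.
# Columns: key_index  definition  min_count
# Keys needing constructs outside the language are marked unsupported
# and are permanently 0.
1	isotope	1
2	unsupported	1
3	unsupported	1
4	unsupported	1
5	unsupported	1
6	unsupported	1
7	unsupported	1
8	hetring:4	1
9	unsupported	1
10	unsupported	1
11	ring:4	1
12	unsupported	1
13	unsupported	1
14	pattern:SS	1
15	unsupported	1
16	hetring:3	1
17	pattern:C#C	1
18	unsupported	1
19	ring:7	1
20	element:Si	1
21	unsupported	1
22	ring:3	1
23	unsupported	1
24	pattern:NO	1
25	unsupported	1
26	unsupported	1
27	element:I	1
28	unsupported	1
29	element:P	1
30	unsupported	1
31	unsupported	1
32	unsupported	1
33	unsupported	1
34	unsupported	1
35	unsupported	1
36	elementring:S	1
37	unsupported	1
38	unsupported	1
39	unsupported	1
40	pattern:OS	1
41	pattern:C#N	1
42	element:F	1
43	unsupported	1
44	unsupported	1
45	unsupported	1
46	element:Br	1
47	unsupported	1
48	unsupported	1
49	charged	1
50	unsupported	1
51	unsupported	1
52	unsupported	1
53	unsupported	1
54	unsupported	1
55	unsupported	1
56	unsupported	1
57	elementring:O	1
58	unsupported	1
59	unsupported	1
60	pattern:S=O	1
61	unsupported	1
62	unsupported	1
63	pattern:N=O	1
64	unsupported	1
65	unsupported	1
66	unsupported	1
67	unsupported	1
68	unsupported	1
69	unsupported	1
70	unsupported	1
71	unsupported	1
72	unsupported	1
73	unsupported	1
74	unsupported	1
75	unsupported	1
76	unsupported	1
77	unsupported	1
78	pattern:C=N	1
79	unsupported	1
80	unsupported	1
81	unsupported	1
82	unsupported	1
83	hetring:5	1
84	elementh:N:2:eq	1
85	unsupported	1
86	unsupported	1
87	unsupported	1
88	element:S	1
89	unsupported	1
90	unsupported	1
91	unsupported	1
92	unsupported	1
93	unsupported	1
94	unsupported	1
95	unsupported	1
96	ring:5	1
97	unsupported	1
98	hetring:6	1
99	pattern:C=C	1
100	unsupported	1
101	unsupported	1
102	unsupported	1
103	element:Cl	1
104	unsupported	1
105	unsupported	1
106	unsupported	1
107	unsupported	1
108	unsupported	1
109	unsupported	1
110	unsupported	1
111	unsupported	1
112	unsupported	1
113	unsupported	1
114	unsupported	1
115	unsupported	1
116	unsupported	1
117	unsupported	1
118	unsupported	1
119	unsupported	1
120	unsupported	1
121	unsupported	1
122	unsupported	1
123	unsupported	1
124	hetpair	1
125	aromring	2
126	unsupported	1
127	unsupported	1
128	unsupported	1
129	unsupported	1
130	hetpair	2
131	unsupported	1
132	unsupported	1
133	unsupported	1
134	unsupported	1
135	unsupported	1
136	unsupported	1
137	unsupported	1
138	unsupported	1
139	elementh:O:1:ge	1
140	element:O	4
141	elementh:C:3:eq	3
142	element:N	2
143	unsupported	1
144	unsupported	1
145	ring:6	2
146	element:O	3
147	unsupported	1
148	unsupported	1
149	elementh:C:3:ge	2
150	unsupported	1
151	elementh:N:1:ge	1
152	unsupported	1
153	unsupported	1
154	pattern:C=O	1
155	unsupported	1
156	unsupported	1
157	pattern:CO	1
158	pattern:CN	1
159	element:O	2
160	elementh:C:3:ge	1
161	element:N	1
162	aromatom	1
163	ring:6	1
164	element:O	1
165	ringatom	1
166	fragments	2
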