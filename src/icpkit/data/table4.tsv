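# Clinical laboratory 2, 250 specimens, icp. result classes; no concurrent
# cytogenetic analysis was run, so those columns are empty.
# Transcription corrections: the class for specimens 245-247 is recorded as
# 'icp.69,XXX or XXY' (the source row reads 'icp.69, or XXY', dropping the
# first alternative); the minus sign in specimen 219 is ASCII.
# Per-row female/male tallies are not transcribed per specimen.
specimen_id	cytogenetic_result	icp_result	concordant
1		icp.46,XX or XY	
2		icp.46,XX or XY	
3		icp.46,XX or XY	
4		icp.46,XX or XY	
5		icp.46,XX or XY	
6		icp.46,XX or XY	
7		icp.46,XX or XY	
8		icp.46,XX or XY	
9		icp.46,XX or XY	
10		icp.46,XX or XY	
11		icp.46,XX or XY	
12		icp.46,XX or XY	
13		icp.46,XX or XY	
14		icp.46,XX or XY	
15		icp.46,XX or XY	
16		icp.46,XX or XY	
17		icp.46,XX or XY	
18		icp.46,XX or XY	
19		icp.46,XX or XY	
20		icp.46,XX or XY	
21		icp.46,XX or XY	
22		icp.46,XX or XY	
23		icp.46,XX or XY	
24		icp.46,XX or XY	
25		icp.46,XX or XY	
26		icp.46,XX or XY	
27		icp.46,XX or XY	
28		icp.46,XX or XY	
29		icp.46,XX or XY	
30		icp.46,XX or XY	
31		icp.46,XX or XY	
32		icp.46,XX or XY	
33		icp.46,XX or XY	
34		icp.46,XX or XY	
35		icp.46,XX or XY	
36		icp.46,XX or XY	
37		icp.46,XX or XY	
38		icp.46,XX or XY	
39		icp.46,XX or XY	
40		icp.46,XX or XY	
41		icp.46,XX or XY	
42		icp.46,XX or XY	
43		icp.46,XX or XY	
44		icp.46,XX or XY	
45		icp.46,XX or XY	
46		icp.46,XX or XY	
47		icp.46,XX or XY	
48		icp.46,XX or XY	
49		icp.46,XX or XY	
50		icp.46,XX or XY	
51		icp.46,XX or XY	
52		icp.46,XX or XY	
53		icp.46,XX or XY	
54		icp.46,XX or XY	
55		icp.46,XX or XY	
56		icp.46,XX or XY	
57		icp.46,XX or XY	
58		icp.46,XX or XY	
59		icp.46,XX or XY	
60		icp.46,XX or XY	
61		icp.46,XX or XY	
62		icp.46,XX or XY	
63		icp.46,XX or XY	
64		icp.46,XX or XY	
65		icp.46,XX or XY	
66		icp.46,XX or XY	
67		icp.46,XX or XY	
68		icp.46,XX or XY	
69		icp.46,XX or XY	
70		icp.46,XX or XY	
71		icp.46,XX or XY	
72		icp.46,XX or XY	
73		icp.46,XX or XY	
74		icp.46,XX or XY	
75		icp.46,XX or XY	
76		icp.46,XX or XY	
77		icp.46,XX or XY	
78		icp.46,XX or XY	
79		icp.46,XX or XY	
80		icp.46,XX or XY	
81		icp.46,XX or XY	
82		icp.46,XX or XY	
83		icp.46,XX or XY	
84		icp.46,XX or XY	
85		icp.46,XX or XY	
86		icp.46,XX or XY	
87		icp.46,XX or XY	
88		icp.46,XX or XY	
89		icp.46,XX or XY	
90		icp.46,XX or XY	
91		icp.46,XX or XY	
92		icp.46,XX or XY	
93		icp.46,XX or XY	
94		icp.46,XX or XY	
95		icp.46,XX or XY	
96		icp.46,XX or XY	
97		icp.46,XX or XY	
98		icp.46,XX or XY	
99		icp.46,XX or XY	
100		icp.46,XX or XY	
101		icp.45,X	
102		icp.45,X	
103		icp.45,X	
104		icp.45,X	
105		icp.45,X	
106		icp.45,X	
107		icp.45,X	
108		icp.47,XX or XY,+16	
109		icp.47,XX or XY,+16	
110		icp.47,XX or XY,+16	
111		icp.47,XX or XY,+16	
112		icp.47,XX or XY,+16	
113		icp.47,XX or XY,+16	
114		icp.47,XX or XY,+16	
115		icp.47,XX or XY,+16	
116		icp.47,XX or XY,+16	
117		icp.47,XX or XY,+16	
118		icp.47,XX or XY,+16	
119		icp.47,XX or XY,+16	
120		icp.47,XX or XY,+16	
121		icp.47,XX or XY,+16	
122		icp.47,XX or XY,+16	
123		icp.47,XX or XY,+16	
124		icp.47,XX or XY,+16	
125		icp.47,XX or XY,+16	
126		icp.47,XX or XY,+16	
127		icp.47,XX or XY,+16	
128		icp.47,XX or XY,+16	
129		icp.47,XX or XY,+16	
130		icp.47,XX or XY,+21	
131		icp.47,XX or XY,+21	
132		icp.47,XX or XY,+21	
133		icp.47,XX or XY,+21	
134		icp.47,XX or XY,+21	
135		icp.47,XX or XY,+21	
136		icp.47,XX or XY,+21	
137		icp.47,XX or XY,+21	
138		icp.47,XX or XY,+21	
139		icp.47,XX or XY,+21	
140		icp.47,XX or XY,+21	
141		icp.47,XX or XY,+21	
142		icp.47,XX or XY,+21	
143		icp.47,XX or XY,+21	
144		icp.47,XX or XY,+21	
145		icp.47,XX or XY,+21	
146		icp.47,XX or XY,+21	
147		icp.47,XX or XY,+21	
148		icp.47,XX or XY,+21	
149		icp.47,XX or XY,+21	
150		icp.47,XX or XY,+21	
151		icp.47,XX or XY,+21	
152		icp.47,XX or XY,+21	
153		icp.47,XX or XY,+21	
154		icp.47,XX or XY,+21	
155		icp.47,XX or XY,+21	
156		icp.47,XX or XY,+21	
157		icp.47,XX or XY,+21	
158		icp.47,XX or XY,+21	
159		icp.47,XX or XY,+21	
160		icp.47,XX or XY,+21	
161		icp.47,XX or XY,+21	
162		icp.47,XX or XY,+21	
163		icp.47,XX or XY,+21	
164		icp.47,XX or XY,+21	
165		icp.47,XX or XY,+21	
166		icp.47,XX or XY,+21	
167		icp.47,XX or XY,+21	
168		icp.47,XX or XY,+21	
169		icp.47,XX or XY,+21	
170		icp.47,XX or XY,+21	
171		icp.47,XX or XY,+21	
172		icp.47,XX or XY,+21	
173		icp.47,XX or XY,+21	
174		icp.47,XX or XY,+21	
175		icp.47,XX or XY,+21	
176		icp.47,XX or XY,+21	
177		icp.47,XX or XY,+21	
178		icp.47,XX or XY,+21	
179		icp.47,XX or XY,+21	
180		icp.47,XX or XY,+21	
181		icp.47,XX or XY,+21	
182		icp.47,XX or XY,+21	
183		icp.47,XX or XY,+21	
184		icp.47,XX or XY,+21	
185		icp.47,XX or XY,+21	
186		icp.47,XX or XY,+21	
187		icp.47,XX or XY,+21	
188		icp.47,XX or XY,+21	
189		icp.47,XX or XY,+21	
190		icp.47,XX or XY,+21	
191		icp.47,XX or XY,+21	
192		icp.47,XX or XY,+21	
193		icp.47,XX or XY,+21	
194		icp.47,XX or XY,+21	
195		icp.47,XX or XY,+21	
196		icp.47,XX or XY,+21	
197		icp.47,XX or XY,+21	
198		icp.47,XX or XY,+21	
199		icp.47,XX or XY,+21	
200		icp.92,XXYY	
201		icp.92,XXYY	
202		icp.92,XXXX/46,XX	
203		icp.47,XX or XY,+13	
204		icp.47,XX or XY,+13	
205		icp.47,XX or XY,+13	
206		icp.47,XX or XY,+13	
207		icp.47,XX or XY,+13	
208		icp.47,XX or XY,+13	
209		icp.47,XX or XY,+13	
210		icp.47,XX or XY,+13	
211		icp.47,XX or XY,+13	
212		icp.47,XX or XY,+13	
213		icp.47,XX or XY,+13	
214		icp.47,XX or XY,+18	
215		icp.47,XX or XY,+18	
216		icp.47,XX or XY,+18	
217		icp.47,XX or XY,+18	
218		icp.47,XX or XY,+18	
219		icp.45,XY,-16	
220		icp.47,XX or XY,+14	
221		icp.47,XX or XY,+14	
222		icp.47,XX,+15	
223		icp.47,XX,+15	
224		icp.47,XX,+22	
225		icp.47,XX,+22	
226		icp.47,XY,+4	
227		icp.47,XX,+19	
228		icp.47,XX,+20	
229		icp.48,XX,+7,+16	
230		icp.48,XX,+13,+16	
231		icp.48,XXY,+15	
232		icp.48,XXY,+16	
233		icp.47,XXX or XXY	
234		icp.47,XXX or XXY	
235		icp.46,XX,t(2;18)(p?;q?)	
236		icp.46,XX,t(12;14)(p?;q?)	
237		icp.46,XY,der(11)t(1;11)(q?;p?)	
238		icp.46,XY,del(9)(p?)	
239		icp.46,XY,del(9)(p?)	
240		icp.46,XY,del(16)(q?)	
241		icp.46,XY,del(16)(q?)	
242		icp.47,XX,der(14;21),+21	
243		icp.46,XX,der(4)t(4;21)(q?;q?)	
244		icp.46,XX,del(10)(p?)	
245		icp.69,XXX or XXY	
246		icp.69,XXX or XXY	
247		icp.69,XXX or XXY	
248		icp.47,XY,+8	
249		icp.92,XXXX or XXYY	
250		icp.92,XXXX or XXYY	
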