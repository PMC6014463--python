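# Initial validation set, 43 specimens; ICP results in the legacy phrase dialect.
specimen_id	cytogenetic_result	icp_result	concordant
1	Normal	Normal	Yes
2	Normal	Normal	Yes
3	Normal	Normal	Yes
4	Normal	Normal	Yes
5	Normal	Normal	Yes
6	Normal	Normal	Yes
7	Normal	Normal	Yes
8	Normal	Normal	Yes
9	Normal	Normal	Yes
10	Normal	Normal	Yes
11	Trisomy 16	Trisomy 16	Yes
12	Normal	Normal	Yes
13	Monosomy X	Monosomy X,del(17q)	Yes, and new changes
14	Trisomy 18	Trisomy 18	Yes
15	Triploid	Triploid	Yes
16	Normal female	Normal male/female	Discordant
17	Normal female	Trisomy 22 (6 cells)	Discordant
18	Normal	Normal	Yes
19	+21,der t(14;21)	+21,der t(14;21)	Yes
20	+15,der(13;15)	+15,der(13;15)	Yes
21	+21,der t(14;21)	+21,der t(14;21)	Yes
22	+13,der(13;14)	+13,der(13;14)	Yes
23	+21,der t(14;21)	+21,der t(14;21)	Yes
24	+14,t(13;22)	+14	Discordant
25	+21,der t(14;21)	+21,der t(14;21)	Yes
26	Normal	Normal	Yes
27	Male trisomy 16	Normal female	Discordant
28	Normal	Normal	Yes
29	Trisomy 10	Trisomy 10	Yes
30	Normal	Normal	Yes
31	Male trisomy 16	Normal female	Discordant
32	Trisomy 10	Trisomy 10	Yes
33	Normal	Normal	Yes
34	Tetraploid	Tetraploid	Yes
35	Normal	Normal	Yes
36	Trisomy 21	Trisomy 21	Yes
37	Culture Failure	Normal	New result
38	Normal	Normal	Yes
39	Normal	Normal	Yes
40	Normal	Normal	Yes
41	Normal	Normal	Yes
42	Trisomy 21	Trisomy 21	Yes
43	Culture Failure	Normal	New result
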