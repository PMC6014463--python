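# Initial commercial laboratory validation, 40 specimens; legacy phrase dialect.
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
11	Triploid	Triploid	Yes
12	Monosomy X	Monosomy X	Yes
13	Trisomy 13	Trisomy 13	Yes
14	Tetraploid	Tetraploid	Yes
15	Monosomy X	Monosomy X,del(Xq)	Concordant, new change
16	Tetraploid	Tetraploid	Yes
17	Tetraploid (mosaic 35%)	Tetraploid (mosaic)	Yes
18	Tetraploid	Tetraploid	Yes
19	Trisomy 18	Trisomy 18	Yes
20	Monosomy X	Monosomy X	Yes
21	Monosomy X	Monosomy X	Yes
22	Tetraploid	Tetraploid	Yes
23	Tetraploid	Tetraploid	Yes
24	Triploid	Triploid	Yes
25	Trisomy 21	Trisomy 21	Yes
26	Tetraploid	Tetraploid	Yes
27	Triploid	Triploid	Yes
28	Trisomy 13	Trisomy 13	Yes
29	Monosomy X	Monosomy X	Yes
30	Trisomy 18	Trisomy 18	Yes
31	Trisomy 21	Trisomy 21, t(2;10)	Concordant, new change
32	Monosomy X	Monosomy X	Yes
33	Trisomy 21	Trisomy 21	Yes
34	Monosomy X	Monosomy X	Yes
35	Monosomy X	Monosomy X	Yes
36	Trisomy 21	Trisomy 21	Yes
37	Tetraploid	Tetraploid	Yes
38	Tetraploid	Tetraploid	Yes
39	Monosomy X	Monosomy X	Yes
40	Monosomy X	Monosomy X	Yes
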