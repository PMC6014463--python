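# Clinical laboratory 1, 41 specimens; icp. nomenclature, spacing as printed.
specimen_id	cytogenetic_result	icp_result	concordant
1	icp.46,XY,der(13;14)(q10;q10),+14	icp.46,XY,der(13;14)(q10;q10),+14	Yes
2	45,X	icp.45,X	Yes
3	45,X	icp.45,X	Yes
4	46,XY,del(4)(p15.2p16.3)	icp.46,XY,del(4)(pter)	Yes
5	47,XX,+15	icp.47,XX,+15	Yes
6	69,XXX	icp.69,XXX	Yes
7	47, XY, +13	icp.47, XY, +13	Yes
8	45,X	icp.45,X	Yes
9	47,XX,+22	icp.47,XX,+22	Yes
10	46, XX	icp.46,XX	Yes
11	46,XY	icp.46,XY	Yes
12	46, XX	icp.46,XX	Yes
13	46,XX,add(18)(q23)	icp.46,XX,der(18)t(7;18)(p?;q?)	Yes and identified change
14	47,XX,+18	icp.47,XX,+18	Yes
15	46,XY	icp.46,XY	Yes
16	47,XX,+22	icp.47,XX,+22	Yes
17	46,XY	icp.46,XY	Yes
18	46, XX	icp.46,XX	Yes
19	46,XY	icp.46,XY	Yes
20	69,XXX	icp.69,XXX	Yes
21	47,XX,+21	icp.47,XX,+21	Yes
22	46,XY	icp.46,XY	Yes
23	47,XY,+16	icp.47,XY,+16	Yes
24	45,X	icp.45,X	Yes
25	45,X	icp.45,X	Yes
26	46, XX	icp.46,XX	Yes
27	46,XY	icp.46,XY	Yes
28	46,XY	icp.46,XY	Yes
29	46, XX	icp.46,XX	Yes
30	46, XX	icp.46,XX	Yes
31	46, XX	icp.46,XX	Yes
32	47,XY,t(2;11)(q33;q13),+22	icp.47,XY,t(2;11)(q?;q?),+22	Yes
33	46, XX	icp.46,XX	Yes
34	47,XX,+21	icp.47,XX,+21	Yes
35	46, XX	icp.46,XX	Yes
36	46,XY	icp.46,XY	Yes
37	46, XX	icp.46,XX	Yes
38	47, XY, +21	icp.47, XY, +21	Yes
39	69,XXY	icp.69,XXY	Yes
40	47,XY, +20	icp.47,XY, +20	Yes
41	46, XX	icp.46,XX	Yes
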