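0	1
1	1
2	1
3	1
4	1
5	1
6	1
7	1
8	1
9	2
10	1
11	1
12	1
13	1
14	2
15	2
16	1
17	1
18	2
19	1
20	2
21	1
22	2
23	2
24	2
25	2
26	2
27	2
28	2
29	2
30	2
31	2
32	2
33	2
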