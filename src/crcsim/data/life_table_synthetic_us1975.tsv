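age	q_male	q_female
0	0.013000	0.011000
1	0.000400	0.000300
2	0.000400	0.000300
3	0.000400	0.000300
4	0.000400	0.000300
5	0.000400	0.000300
6	0.000400	0.000300
7	0.000400	0.000300
8	0.000400	0.000300
9	0.000400	0.000300
10	0.000400	0.000300
11	0.000400	0.000300
12	0.000400	0.000300
13	0.000400	0.000300
14	0.000400	0.000300
15	0.001155	0.000599
16	0.001170	0.000609
17	0.001186	0.000620
18	0.001204	0.000631
19	0.001224	0.000644
20	0.001246	0.000659
21	0.001270	0.000674
22	0.001296	0.000691
23	0.001325	0.000710
24	0.001357	0.000731
25	0.001392	0.000754
26	0.001430	0.000779
27	0.001472	0.000806
28	0.001518	0.000836
29	0.001568	0.000870
30	0.001624	0.000906
31	0.001684	0.000946
32	0.001751	0.000990
33	0.001824	0.001038
34	0.001905	0.001091
35	0.001993	0.001150
36	0.002089	0.001214
37	0.002196	0.001284
38	0.002312	0.001361
39	0.002440	0.001446
40	0.002580	0.001539
41	0.002734	0.001642
42	0.002904	0.001754
43	0.003089	0.001878
44	0.003293	0.002014
45	0.003516	0.002163
46	0.003761	0.002327
47	0.004030	0.002507
48	0.004326	0.002705
49	0.004650	0.002922
50	0.005006	0.003161
51	0.005396	0.003423
52	0.005824	0.003711
53	0.006295	0.004028
54	0.006811	0.004375
55	0.007377	0.004757
56	0.007998	0.005177
57	0.008681	0.005638
58	0.009429	0.006144
59	0.010251	0.006700
60	0.011152	0.007311
61	0.012142	0.007983
62	0.013228	0.008720
63	0.014419	0.009530
64	0.015727	0.010420
65	0.017163	0.011398
66	0.018738	0.012472
67	0.020466	0.013652
68	0.022364	0.014949
69	0.024446	0.016373
70	0.026731	0.017937
71	0.029239	0.019656
72	0.031991	0.021544
73	0.035011	0.023618
74	0.038326	0.025896
75	0.041964	0.028399
76	0.045956	0.031149
77	0.050338	0.034170
78	0.055147	0.037488
79	0.060424	0.041134
80	0.066215	0.045139
81	0.072571	0.049538
82	0.079547	0.054371
83	0.087202	0.059681
84	0.095604	0.065514
85	0.104824	0.071921
86	0.114943	0.078961
87	0.126048	0.086694
88	0.138235	0.095189
89	0.151610	0.104521
90	0.166289	0.114774
91	0.182398	0.126037
92	0.200078	0.138409
93	0.219480	0.152002
94	0.240773	0.166934
95	0.264142	0.183337
96	0.289789	0.201358
97	0.317934	0.221154
98	0.348823	0.242902
99	0.382723	0.266793
100	1.000000	1.000000
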