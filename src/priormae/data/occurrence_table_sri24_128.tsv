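# units: permille
region_id	et	tc	wt
1	4.752	6.232	7.804
2	6.076	7.487	9.324
3	4.488	5.667	6.900
4	7.042	7.193	7.949
5	4.258	4.047	4.198
6	2.253	3.679	3.666
7	5.058	5.902	7.232
8	7.983	8.575	8.887
9	4.697	4.000	4.069
10	4.302	4.591	4.235
11	10.660	11.250	12.304
12	12.720	13.980	14.909
13	6.800	6.684	7.671
14	8.131	8.618	8.160
15	8.506	7.635	7.178
16	6.499	6.783	6.170
17	13.663	14.048	16.044
18	17.307	17.339	17.131
19	3.260	4.923	5.407
20	3.897	4.862	5.722
21	7.835	8.926	9.186
22	7.424	9.238	8.825
23	5.723	7.193	6.791
24	8.352	8.358	8.053
25	5.593	5.984	6.282
26	5.275	5.768	6.391
27	3.380	3.943	3.972
28	2.602	3.767	3.784
29	22.308	22.074	20.767
30	22.077	23.383	20.966
31	15.676	14.889	13.405
32	17.266	15.530	13.671
33	9.670	9.221	8.695
34	10.018	8.920	9.074
35	8.562	6.641	5.224
36	7.492	5.694	4.343
37	22.961	19.311	16.840
38	20.812	18.402	15.837
39	10.437	8.829	8.304
40	8.959	8.447	7.602
41	20.511	17.402	15.713
42	19.540	18.639	16.355
43	3.381	3.224	3.248
44	2.699	2.668	2.584
45	5.139	4.690	4.523
46	4.073	3.794	3.657
47	1.932	1.842	1.673
48	2.241	1.949	1.706
49	6.592	5.891	5.982
50	4.727	4.686	5.243
51	4.827	4.206	4.233
52	4.906	4.636	4.816
53	1.949	1.836	1.902
54	2.332	2.017	1.918
55	7.666	6.745	6.341
56	6.645	6.265	5.671
57	5.545	6.162	7.175
58	7.017	7.076	8.576
59	6.488	6.475	6.568
60	5.566	5.746	7.283
61	7.063	6.733	6.843
62	7.861	7.588	9.150
63	6.903	6.783	7.793
64	8.235	7.420	7.827
65	6.924	6.237	6.478
66	5.039	5.836	6.568
67	5.838	5.624	5.486
68	5.379	4.854	4.737
69	3.144	3.872	4.267
70	3.148	3.553	4.698
71	17.277	18.222	16.062
72	17.632	19.147	18.173
73	21.153	20.498	20.578
74	22.365	23.167	22.596
75	16.388	16.856	17.372
76	19.246	19.615	18.951
77	10.394	10.765	11.793
78	16.606	14.655	15.036
79	20.442	19.811	21.291
80	23.945	25.019	22.553
81	13.914	14.137	15.073
82	15.253	15.150	14.987
83	18.236	16.137	15.620
84	13.306	13.089	12.785
85	11.423	10.749	11.322
86	9.425	10.035	10.850
87	11.912	10.302	11.184
88	9.728	8.737	8.556
89	9.253	8.937	9.267
90	7.208	7.937	7.986
91	0.382	0.253	0.251
92	0.046	0.066	0.137
93	0.425	0.228	0.177
94	0.000	0.033	0.110
95	0.233	0.461	0.587
96	0.462	0.396	0.585
97	0.234	0.371	0.451
98	0.566	0.627	0.660
99	0.432	0.359	0.365
100	0.346	0.406	0.432
101	0.511	0.250	0.221
102	0.006	0.020	0.108
103	0.443	0.244	0.238
104	0.077	0.102	0.154
105	0.234	0.234	0.324
106	0.297	0.236	0.338
107	0.000	0.048	0.104
108	0.109	0.091	0.130
109	0.571	0.502	0.674
110	0.332	0.496	0.603
111	0.649	0.531	0.665
112	0.385	0.244	0.307
113	0.513	0.320	0.336
114	0.212	0.342	0.395
115	17.195	15.945	14.050
116	8.231	8.323	9.206
117	6.310	7.011	9.164
118	6.761	7.458	9.569
119	19.636	18.910	16.956
120	21.037	20.192	18.556
121	2.881	7.415	6.751
122	3.018	7.112	6.942
123	15.209	15.058	16.662
124	16.987	16.541	18.001
125	7.655	7.821	7.360
126	7.681	8.149	7.542
127	3.154	3.684	3.294
128	3.571	4.070	3.562
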