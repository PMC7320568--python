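# provenance: synthetic reconstruction of the sex-combined (unweighted male/female mean) United States 2016 period life table; log-linear interpolation between approximate recalled anchors; NOT the published SSA table
age,q
0,0.005878
1,0.000393
2,0.000247
3,0.000198
4,0.000159
5,0.000128
6,0.000123
7,0.000119
8,0.000114
9,0.000110
10,0.000106
11,0.000126
12,0.000151
13,0.000180
14,0.000215
15,0.000256
16,0.000319
17,0.000398
18,0.000496
19,0.000618
20,0.000770
21,0.000811
22,0.000853
23,0.000898
24,0.000945
25,0.000995
26,0.001026
27,0.001058
28,0.001091
29,0.001125
30,0.001160
31,0.001210
32,0.001261
33,0.001315
34,0.001371
35,0.001430
36,0.001496
37,0.001564
38,0.001636
39,0.001711
40,0.001790
41,0.001910
42,0.002038
43,0.002174
44,0.002320
45,0.002475
46,0.002731
47,0.003012
48,0.003323
49,0.003666
50,0.004045
51,0.004371
52,0.004723
53,0.005104
54,0.005515
55,0.005960
56,0.006458
57,0.006997
58,0.007581
59,0.008214
60,0.008900
61,0.009605
62,0.010366
63,0.011187
64,0.012074
65,0.013030
66,0.014202
67,0.015480
68,0.016873
69,0.018391
70,0.020045
71,0.021876
72,0.023875
73,0.026056
74,0.028437
75,0.031035
76,0.034176
77,0.037634
78,0.041443
79,0.045637
80,0.050255
81,0.056203
82,0.062855
83,0.070295
84,0.078615
85,0.087920
86,0.098076
87,0.109405
88,0.122042
89,0.136139
90,0.151865
91,0.165722
92,0.180843
93,0.197344
94,0.215350
95,0.235000
96,0.252269
97,0.270806
98,0.290706
99,0.312068
100,0.335000
101,0.358472
102,0.383589
103,0.410465
104,0.439225
105,0.470000
106,0.491032
107,0.513004
108,0.535960
109,0.559944
110,0.585000
111,0.601985
112,0.619463
113,0.637448
114,0.655955
115,0.675000
116,0.689524
117,0.704361
118,0.719518
119,0.735000
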