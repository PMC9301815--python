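# Synthetic UK-style all-persons period life table (annual probability of death).
# Constructed by monotone (PCHIP) log-hazard interpolation through qx anchor
# values typical of the UK national life tables around 2018-2020; NOT official
# statistics. Life expectancy: 80.6 y at birth, 25.4 y at age 58.
age,q_annual
0,0.004000
1,0.000200
2,0.000167
3,0.000144
4,0.000128
5,0.000117
6,0.000109
7,0.000105
8,0.000102
9,0.000100
10,0.000100
11,0.000103
12,0.000111
13,0.000125
14,0.000145
15,0.000170
16,0.000202
17,0.000239
18,0.000279
19,0.000318
20,0.000350
21,0.000376
22,0.000400
23,0.000422
24,0.000444
25,0.000466
26,0.000488
27,0.000511
28,0.000537
29,0.000566
30,0.000600
31,0.000639
32,0.000684
33,0.000733
34,0.000787
35,0.000847
36,0.000913
37,0.000986
38,0.001067
39,0.001154
40,0.001250
41,0.001356
42,0.001476
43,0.001611
44,0.001761
45,0.001927
46,0.002109
47,0.002308
48,0.002524
49,0.002755
50,0.003000
51,0.003255
52,0.003523
53,0.003811
54,0.004132
55,0.004500
56,0.004949
57,0.005469
58,0.006000
59,0.006485
60,0.007000
61,0.007625
62,0.008345
63,0.009156
64,0.010047
65,0.011000
66,0.012006
67,0.013082
68,0.014253
69,0.015546
70,0.017000
71,0.018634
72,0.020457
73,0.022500
74,0.024800
75,0.027400
76,0.030360
77,0.033735
78,0.037569
79,0.041909
80,0.046800
81,0.052351
82,0.058681
83,0.065851
84,0.073913
85,0.082900
86,0.093010
87,0.104437
88,0.117156
89,0.131071
90,0.146000
91,0.162004
92,0.179276
93,0.197722
94,0.217198
95,0.237500
96,0.258595
97,0.280534
98,0.303187
99,0.326399
100,0.350000
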