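age,male,female
18,0.0012,0.0006
19,0.0012,0.0006
20,0.0012,0.0006
21,0.0012,0.0006
22,0.0012,0.0006
23,0.0012,0.0006
24,0.0012,0.0006
25,0.0012,0.0006
26,0.0012,0.0006
27,0.0012,0.0006
28,0.0012,0.0006
29,0.0012,0.0006
30,0.0012,0.0006
31,0.0012,0.0006
32,0.0012,0.000642984
33,0.0012,0.000702131
34,0.00120099,0.000766718
35,0.00130754,0.000837247
36,0.00142354,0.000914264
37,0.00154983,0.000998366
38,0.00168733,0.0010902
39,0.00183702,0.00119049
40,0.002,0.0013
41,0.00217743,0.00141958
42,0.00237061,0.00155017
43,0.00258092,0.00169277
44,0.0028099,0.00184848
45,0.00305918,0.00201852
46,0.00333058,0.0022042
47,0.00362606,0.00240696
48,0.00394776,0.00262837
49,0.00429799,0.00287015
50,0.00467929,0.00313417
51,0.00509443,0.00342248
52,0.00554639,0.0037373
53,0.00603845,0.00408109
54,0.00657416,0.0044565
55,0.0071574,0.00486645
56,0.00779239,0.0053141
57,0.0084837,0.00580294
58,0.00923635,0.00633674
59,0.0100558,0.00691964
60,0.0109479,0.00755617
61,0.0119192,0.00825125
62,0.0129766,0.00901026
63,0.0141278,0.0098391
64,0.0153812,0.0107442
65,0.0167458,0.0117325
66,0.0182314,0.0128118
67,0.0198489,0.0139903
68,0.0216098,0.0152772
69,0.023527,0.0166826
70,0.0256142,0.0182172
71,0.0278866,0.0198929
72,0.0303606,0.0217228
73,0.0330542,0.0237211
74,0.0359866,0.0259031
75,0.0391792,0.0282859
76,0.0426551,0.0308879
77,0.0464394,0.0337292
78,0.0505593,0.0368319
79,0.0550448,0.04022
80,0.0599282,0.0439198
81,0.0652449,0.0479599
82,0.0710332,0.0523716
83,0.077335,0.0571892
84,0.084196,0.0624499
85,0.0916656,0.0681945
86,0.0997979,0.0744676
87,0.108652,0.0813177
88,0.118291,0.088798
89,0.128785,0.0969664
90,0.140211,0.105886
91,0.15265,0.115626
92,0.166193,0.126263
93,0.180937,0.137877
94,0.196989,0.15056
95,0.214465,0.16441
96,0.233492,0.179534
97,0.254207,0.196049
98,0.276759,0.214083
99,0.301312,0.233776
100,0.328044,0.255281
101,0.357147,0.278764
102,0.388832,0.304407
103,0.423328,0.332408
104,0.460884,0.362986
105,0.501773,0.396376
106,0.546288,0.432838
107,0.594754,0.472654
108,0.647518,0.516133
109,0.704964,0.563611
110,0.767507,0.615456
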