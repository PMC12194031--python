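age,sex,q
18,female,0.000111
19,female,0.000122
20,female,0.000134
21,female,0.000147
22,female,0.000162
23,female,0.000178
24,female,0.000196
25,female,0.000215
26,female,0.000236
27,female,0.00026
28,female,0.000286
29,female,0.000314
30,female,0.000346
31,female,0.00038
32,female,0.000418
33,female,0.00046
34,female,0.000506
35,female,0.000556
36,female,0.000611
37,female,0.000672
38,female,0.000739
39,female,0.000813
40,female,0.000894
41,female,0.000983
42,female,0.001081
43,female,0.001189
44,female,0.001307
45,female,0.001438
46,female,0.001581
47,female,0.001738
48,female,0.001912
49,female,0.002102
50,female,0.002312
51,female,0.002542
52,female,0.002795
53,female,0.003074
54,female,0.00338
55,female,0.003717
56,female,0.004088
57,female,0.004495
58,female,0.004943
59,female,0.005436
60,female,0.005977
61,female,0.006573
62,female,0.007228
63,female,0.007948
64,female,0.008741
65,female,0.009612
66,female,0.01057
67,female,0.011623
68,female,0.012781
69,female,0.014055
70,female,0.015456
71,female,0.016996
72,female,0.01869
73,female,0.020552
74,female,0.022601
75,female,0.024853
76,female,0.02733
77,female,0.030053
78,female,0.033049
79,female,0.036342
80,female,0.039964
81,female,0.043947
82,female,0.048326
83,female,0.053143
84,female,0.058439
85,female,0.064263
86,female,0.070667
87,female,0.077709
88,female,0.085454
89,female,0.09397
90,female,0.103335
91,female,0.113633
92,female,0.124958
93,female,0.137411
94,female,0.151105
95,female,0.166164
96,female,0.182724
97,female,0.200934
98,female,0.220959
99,female,0.242979
100,female,0.267195
18,male,0.000177
19,male,0.000195
20,male,0.000214
21,male,0.000235
22,male,0.000259
23,male,0.000285
24,male,0.000313
25,male,0.000344
26,male,0.000378
27,male,0.000416
28,male,0.000457
29,male,0.000503
30,male,0.000553
31,male,0.000608
32,male,0.000669
33,male,0.000736
34,male,0.000809
35,male,0.00089
36,male,0.000978
37,male,0.001076
38,male,0.001183
39,male,0.001301
40,male,0.00143
41,male,0.001573
42,male,0.00173
43,male,0.001902
44,male,0.002092
45,male,0.0023
46,male,0.002529
47,male,0.002781
48,male,0.003059
49,male,0.003363
50,male,0.003699
51,male,0.004067
52,male,0.004473
53,male,0.004918
54,male,0.005409
55,male,0.005948
56,male,0.00654
57,male,0.007192
58,male,0.007909
59,male,0.008697
60,male,0.009564
61,male,0.010517
62,male,0.011565
63,male,0.012718
64,male,0.013985
65,male,0.015379
66,male,0.016911
67,male,0.018597
68,male,0.02045
69,male,0.022488
70,male,0.024729
71,male,0.027194
72,male,0.029904
73,male,0.032884
74,male,0.036161
75,male,0.039765
76,male,0.043728
77,male,0.048085
78,male,0.052878
79,male,0.058147
80,male,0.063942
81,male,0.070315
82,male,0.077322
83,male,0.085028
84,male,0.093502
85,male,0.10282
86,male,0.113067
87,male,0.124335
88,male,0.136726
89,male,0.150352
90,male,0.165336
91,male,0.181813
92,male,0.199933
93,male,0.219858
94,male,0.241768
95,male,0.265863
96,male,0.292358
97,male,0.321495
98,male,0.353534
99,male,0.388767
100,male,0.427511
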