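,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,1.1160,1.0646,0.5774,0.5174,0.8228,1.1185,0.5119,0.9880,0.4430,0.9428,0.8296,0.5698,0.7225,0.5075,0.3989,0.8838,0.7815,1.0570,0.5469,0.5692
C,1.0646,1.0126,0.5718,0.5123,0.7818,1.0787,0.5052,0.9336,0.4410,0.8928,0.7910,0.5643,0.7026,0.5026,0.4005,0.8545,0.7552,0.9997,0.5291,0.5523
D,0.5774,0.5718,0.1413,0.1266,0.4484,0.4898,0.1384,0.5767,0.0917,0.5363,0.4317,0.1394,0.2735,0.1242,0.0565,0.3709,0.3317,0.6104,0.2269,0.2247
E,0.5174,0.5123,0.1266,0.1134,0.4018,0.4388,0.1240,0.5167,0.0822,0.4805,0.3868,0.1249,0.2451,0.1113,0.0507,0.3323,0.2972,0.5469,0.2033,0.2014
F,0.8228,0.7818,0.4484,0.4018,0.6034,0.8374,0.3957,0.7190,0.3465,0.6881,0.6113,0.4425,0.5472,0.3942,0.3157,0.6640,0.5867,0.7701,0.4113,0.4298
G,1.1185,1.0787,0.4898,0.4388,0.8374,1.0707,0.4416,1.0271,0.3664,0.9722,0.8328,0.4833,0.6675,0.4305,0.3152,0.8370,0.7422,1.0951,0.5164,0.5311
H,0.5119,0.5052,0.1384,0.1240,0.3957,0.4416,0.1332,0.5058,0.0928,0.4714,0.3825,0.1365,0.2508,0.1216,0.0626,0.3360,0.3001,0.5359,0.2058,0.2051
I,0.9880,0.9336,0.5767,0.5167,0.7190,1.0271,0.5058,0.8474,0.4494,0.8144,0.7334,0.5690,0.6813,0.5069,0.4154,0.8183,0.7221,0.9093,0.5074,0.5329
K,0.4430,0.4410,0.0917,0.0822,0.3465,0.3664,0.0928,0.4494,0.0559,0.4166,0.3315,0.0905,0.1993,0.0806,0.0275,0.2755,0.2468,0.4750,0.1682,0.1651
L,0.9428,0.8928,0.5363,0.4805,0.6881,0.9722,0.4714,0.8144,0.4166,0.7815,0.7001,0.5292,0.6413,0.4714,0.3831,0.7732,0.6826,0.8733,0.4792,0.5024
M,0.8296,0.7910,0.4317,0.3868,0.6113,0.8328,0.3825,0.7334,0.3315,0.7001,0.6166,0.4260,0.5387,0.3794,0.2988,0.6583,0.5821,0.7847,0.4074,0.4242
N,0.5698,0.5643,0.1394,0.1249,0.4425,0.4833,0.1365,0.5690,0.0905,0.5292,0.4260,0.1376,0.2699,0.1225,0.0558,0.3660,0.3273,0.6023,0.2239,0.2218
P,0.7225,0.7026,0.2735,0.2451,0.5472,0.6675,0.2508,0.6813,0.1993,0.6413,0.5387,0.2699,0.4039,0.2404,0.1628,0.5172,0.4597,0.7247,0.3184,0.3241
Q,0.5075,0.5026,0.1242,0.1113,0.3942,0.4305,0.1216,0.5069,0.0806,0.4714,0.3794,0.1225,0.2404,0.1091,0.0497,0.3260,0.2915,0.5365,0.1995,0.1975
R,0.3989,0.4005,0.0565,0.0507,0.3157,0.3152,0.0626,0.4154,0.0275,0.3831,0.2988,0.0558,0.1628,0.0497,0.0000,0.2337,0.2102,0.4382,0.1422,0.1371
S,0.8838,0.8545,0.3709,0.3323,0.6640,0.8370,0.3360,0.8183,0.2755,0.7732,0.6583,0.3660,0.5172,0.3260,0.2337,0.6525,0.5790,0.8718,0.4023,0.4125
T,0.7815,0.7552,0.3317,0.2972,0.5867,0.7422,0.3001,0.7221,0.2468,0.6826,0.5821,0.3273,0.4597,0.2915,0.2102,0.5790,0.5137,0.7694,0.3571,0.3664
V,1.0570,0.9997,0.6104,0.5469,0.7701,1.0951,0.5359,0.9093,0.4750,0.8733,0.7847,0.6023,0.7247,0.5365,0.4382,0.8718,0.7694,0.9754,0.5405,0.5673
W,0.5469,0.5291,0.2269,0.2033,0.4113,0.5164,0.2058,0.5074,0.1682,0.4792,0.4074,0.2239,0.3184,0.1995,0.1422,0.4023,0.3571,0.5405,0.2480,0.2541
Y,0.5692,0.5523,0.2247,0.2014,0.4298,0.5311,0.2051,0.5329,0.1651,0.5024,0.4242,0.2218,0.3241,0.1975,0.1371,0.4125,0.3664,0.5673,0.2541,0.2594
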