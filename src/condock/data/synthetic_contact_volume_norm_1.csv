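,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,0.7812,0.7804,0.1100,0.0968,0.5760,0.6059,0.1181,0.7746,0.0513,0.7144,0.5592,0.1084,0.3166,0.0946,0.0000,0.4578,0.4079,0.8363,0.2500,0.2492
C,0.7804,0.7876,0.1112,0.0989,0.5973,0.5937,0.1213,0.7985,0.0529,0.7364,0.5757,0.1097,0.3201,0.0968,0.0000,0.4574,0.4131,0.8548,0.2614,0.2586
D,0.1100,0.1112,0.0157,0.0140,0.0846,0.0835,0.0172,0.1130,0.0075,0.1042,0.0815,0.0155,0.0452,0.0137,0.0000,0.0645,0.0583,0.1208,0.0371,0.0366
E,0.0968,0.0989,0.0140,0.0126,0.0776,0.0720,0.0155,0.1029,0.0068,0.0949,0.0741,0.0138,0.0403,0.0124,0.0000,0.0568,0.0521,0.1090,0.0343,0.0336
F,0.5760,0.5973,0.0846,0.0776,0.4894,0.4176,0.0965,0.6426,0.0426,0.5926,0.4619,0.0838,0.2440,0.0763,0.0000,0.3378,0.3162,0.6715,0.2194,0.2125
G,0.6059,0.5937,0.0835,0.0720,0.4176,0.4878,0.0872,0.5675,0.0375,0.5233,0.4104,0.0821,0.2400,0.0701,0.0000,0.3549,0.3084,0.6218,0.1788,0.1804
H,0.1181,0.1213,0.0172,0.0155,0.0965,0.0872,0.0192,0.1276,0.0085,0.1176,0.0918,0.0170,0.0495,0.0153,0.0000,0.0693,0.0640,0.1345,0.0428,0.0418
I,0.7746,0.7985,0.1130,0.1029,0.6426,0.5675,0.1276,0.8474,0.0562,0.7815,0.6095,0.1118,0.3258,0.1011,0.0000,0.4542,0.4218,0.8905,0.2865,0.2788
K,0.0513,0.0529,0.0075,0.0068,0.0426,0.0375,0.0085,0.0562,0.0037,0.0518,0.0404,0.0074,0.0216,0.0067,0.0000,0.0301,0.0279,0.0590,0.0190,0.0185
L,0.7144,0.7364,0.1042,0.0949,0.5926,0.5233,0.1176,0.7815,0.0518,0.7207,0.5621,0.1031,0.3005,0.0932,0.0000,0.4189,0.3890,0.8212,0.2642,0.2571
M,0.5592,0.5757,0.0815,0.0741,0.4619,0.4104,0.0918,0.6095,0.0404,0.5621,0.4385,0.0806,0.2349,0.0728,0.0000,0.3279,0.3040,0.6412,0.2057,0.2004
N,0.1084,0.1097,0.0155,0.0138,0.0838,0.0821,0.0170,0.1118,0.0074,0.1031,0.0806,0.0153,0.0446,0.0135,0.0000,0.0635,0.0576,0.1194,0.0367,0.0363
P,0.3166,0.3201,0.0452,0.0403,0.2440,0.2400,0.0495,0.3258,0.0216,0.3005,0.2349,0.0446,0.1301,0.0394,0.0000,0.1855,0.1680,0.3482,0.1069,0.1057
Q,0.0946,0.0968,0.0137,0.0124,0.0763,0.0701,0.0153,0.1011,0.0067,0.0932,0.0728,0.0135,0.0394,0.0121,0.0000,0.0554,0.0510,0.1069,0.0338,0.0331
R,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000
S,0.4578,0.4574,0.0645,0.0568,0.3378,0.3549,0.0693,0.4542,0.0301,0.4189,0.3279,0.0635,0.1855,0.0554,0.0000,0.2683,0.2391,0.4903,0.1467,0.1461
T,0.4079,0.4131,0.0583,0.0521,0.3162,0.3084,0.0640,0.4218,0.0279,0.3890,0.3040,0.0576,0.1680,0.0510,0.0000,0.2391,0.2169,0.4503,0.1387,0.1369
V,0.8363,0.8548,0.1208,0.1090,0.6715,0.6218,0.1345,0.8905,0.0590,0.8212,0.6412,0.1194,0.3482,0.1069,0.0000,0.4903,0.4503,0.9429,0.2970,0.2911
W,0.2500,0.2614,0.0371,0.0343,0.2194,0.1788,0.0428,0.2865,0.0190,0.2642,0.2057,0.0367,0.1069,0.0338,0.0000,0.1467,0.1387,0.2970,0.0992,0.0954
Y,0.2492,0.2586,0.0366,0.0336,0.2125,0.1804,0.0418,0.2788,0.0185,0.2571,0.2004,0.0363,0.1057,0.0331,0.0000,0.1461,0.1369,0.2911,0.0954,0.0922
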