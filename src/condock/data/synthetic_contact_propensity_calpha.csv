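,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,0.7000,0.7389,0.4056,0.4056,0.7556,0.5778,0.4222,0.8500,0.3833,0.8111,0.7056,0.4056,0.5111,0.4056,0.3500,0.5556,0.5611,0.8333,0.5500,0.5278
C,0.7389,0.7778,0.4444,0.4444,0.7944,0.6167,0.4611,0.8889,0.4222,0.8500,0.7444,0.4444,0.5500,0.4444,0.3889,0.5944,0.6000,0.8722,0.5889,0.5667
D,0.4056,0.4444,0.1111,0.1111,0.4611,0.2833,0.1278,0.5556,0.0889,0.5167,0.4111,0.1111,0.2167,0.1111,0.0556,0.2611,0.2667,0.5389,0.2556,0.2333
E,0.4056,0.4444,0.1111,0.1111,0.4611,0.2833,0.1278,0.5556,0.0889,0.5167,0.4111,0.1111,0.2167,0.1111,0.0556,0.2611,0.2667,0.5389,0.2556,0.2333
F,0.7556,0.7944,0.4611,0.4611,0.8111,0.6333,0.4778,0.9056,0.4389,0.8667,0.7611,0.4611,0.5667,0.4611,0.4056,0.6111,0.6167,0.8889,0.6056,0.5833
G,0.5778,0.6167,0.2833,0.2833,0.6333,0.4556,0.3000,0.7278,0.2611,0.6889,0.5833,0.2833,0.3889,0.2833,0.2278,0.4333,0.4389,0.7111,0.4278,0.4056
H,0.4222,0.4611,0.1278,0.1278,0.4778,0.3000,0.1444,0.5722,0.1056,0.5333,0.4278,0.1278,0.2333,0.1278,0.0722,0.2778,0.2833,0.5556,0.2722,0.2500
I,0.8500,0.8889,0.5556,0.5556,0.9056,0.7278,0.5722,1.0000,0.5333,0.9611,0.8556,0.5556,0.6611,0.5556,0.5000,0.7056,0.7111,0.9833,0.7000,0.6778
K,0.3833,0.4222,0.0889,0.0889,0.4389,0.2611,0.1056,0.5333,0.0667,0.4944,0.3889,0.0889,0.1944,0.0889,0.0333,0.2389,0.2444,0.5167,0.2333,0.2111
L,0.8111,0.8500,0.5167,0.5167,0.8667,0.6889,0.5333,0.9611,0.4944,0.9222,0.8167,0.5167,0.6222,0.5167,0.4611,0.6667,0.6722,0.9444,0.6611,0.6389
M,0.7056,0.7444,0.4111,0.4111,0.7611,0.5833,0.4278,0.8556,0.3889,0.8167,0.7111,0.4111,0.5167,0.4111,0.3556,0.5611,0.5667,0.8389,0.5556,0.5333
N,0.4056,0.4444,0.1111,0.1111,0.4611,0.2833,0.1278,0.5556,0.0889,0.5167,0.4111,0.1111,0.2167,0.1111,0.0556,0.2611,0.2667,0.5389,0.2556,0.2333
P,0.5111,0.5500,0.2167,0.2167,0.5667,0.3889,0.2333,0.6611,0.1944,0.6222,0.5167,0.2167,0.3222,0.2167,0.1611,0.3667,0.3722,0.6444,0.3611,0.3389
Q,0.4056,0.4444,0.1111,0.1111,0.4611,0.2833,0.1278,0.5556,0.0889,0.5167,0.4111,0.1111,0.2167,0.1111,0.0556,0.2611,0.2667,0.5389,0.2556,0.2333
R,0.3500,0.3889,0.0556,0.0556,0.4056,0.2278,0.0722,0.5000,0.0333,0.4611,0.3556,0.0556,0.1611,0.0556,0.0000,0.2056,0.2111,0.4833,0.2000,0.1778
S,0.5556,0.5944,0.2611,0.2611,0.6111,0.4333,0.2778,0.7056,0.2389,0.6667,0.5611,0.2611,0.3667,0.2611,0.2056,0.4111,0.4167,0.6889,0.4056,0.3833
T,0.5611,0.6000,0.2667,0.2667,0.6167,0.4389,0.2833,0.7111,0.2444,0.6722,0.5667,0.2667,0.3722,0.2667,0.2111,0.4167,0.4222,0.6944,0.4111,0.3889
V,0.8333,0.8722,0.5389,0.5389,0.8889,0.7111,0.5556,0.9833,0.5167,0.9444,0.8389,0.5389,0.6444,0.5389,0.4833,0.6889,0.6944,0.9667,0.6833,0.6611
W,0.5500,0.5889,0.2556,0.2556,0.6056,0.4278,0.2722,0.7000,0.2333,0.6611,0.5556,0.2556,0.3611,0.2556,0.2000,0.4056,0.4111,0.6833,0.4000,0.3778
Y,0.5278,0.5667,0.2333,0.2333,0.5833,0.4056,0.2500,0.6778,0.2111,0.6389,0.5333,0.2333,0.3389,0.2333,0.1778,0.3833,0.3889,0.6611,0.3778,0.3556
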