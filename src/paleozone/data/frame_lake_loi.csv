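depth,water,organics,carbonates,minerogenics
1,0.01,0.35,0.03,0.63
2,0.03,0.36,0.02,0.62
3,0.03,0.31,0.03,0.66
4,0.05,0.34,0.01,0.65
5,0.04,0.34,0.02,0.64
6,0.05,0.4,0.03,0.57
7,0.06,0.34,0.02,0.64
8,0.06,0.32,0.02,0.66
9,0.08,0.21,0.03,0.76
10,0.12,0.2,0.02,0.79
11,0.18,0.1,0.02,0.88
12,0.16,0.12,0.02,0.86
13,0.16,0.15,0.02,0.83
14,0.16,0.15,0.02,0.83
15,0.12,0.18,0.02,0.8
16,0.09,0.24,0.03,0.73
17,0.08,0.33,0.03,0.64
18,0.11,0.28,0.02,0.7
19,0.1,0.32,0.02,0.66
20,0.1,0.35,0.02,0.63
21,0.08,0.37,0.02,0.61
22,0.08,0.35,0.03,0.63
23,0.09,0.35,0.03,0.62
24,0.09,0.35,0.02,0.63
25,0.1,0.35,0.02,0.63
26,0.1,0.36,0.02,0.62
27,0.1,0.35,0.02,0.63
28,0.12,0.38,0.02,0.6
29,0.09,0.35,0.02,0.63
30,0.09,0.33,0.02,0.64
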