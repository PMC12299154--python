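mil,preg_rate_primiparous,preg_rate_multiparous,mortality_primiparous,inv_cull_primiparous,mortality_multiparous,inv_cull_multiparous
1,0,0,0.004,0.006,0.012,0.018
2,0.2368,0.2103,0.004,0.006,0.011,0.017
3,0.1888,0.1795,0.004,0.005,0.011,0.016
4,0.1363,0.1429,0.003,0.005,0.010,0.015
5,0.0995,0.1107,0.003,0.005,0.010,0.014
6,0.0748,0.0875,0.003,0.004,0.009,0.013
7,0.0573,0.068,0.003,0.004,0.009,0.011
8,0.0449,0.0535,0.003,0.003,0.008,0.010
9,0.0428,0.0527,0.003,0.003,0.008,0.009
10,0.0458,0.0546,0.002,0.003,0.007,0.008
11,0.0493,0.0516,0.002,0.002,0.007,0.007
12,0.0498,0.0541,0.002,0.002,0.006,0.006
13,0.0517,0.0557,0.002,0.002,0.006,0.006
14,0.0505,0.0575,0.002,0.002,0.006,0.007
15,0.0501,0.0549,0.002,0.002,0.006,0.007
16,0,0,0.002,0.002,0.007,0.007
17,0,0,0.002,0.002,0.007,0.007
18,0,0,0.002,0.003,0.007,0.008
19,0,0,0.002,0.003,0.007,0.008
20,0,0,0.002,0.003,0.007,0.008
21,0,0,0.002,0.003,0.007,0.008
22,0,0,0.002,0.003,0.007,0.009
23,0,0,0.002,0.003,0.007,0.009
24,0,0,0.0025,0.003,0.008,0.009
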