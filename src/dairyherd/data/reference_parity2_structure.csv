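mil,preg0,preg1,preg2,preg3,preg4,preg5,preg6,preg7,preg8
1,0.024984,,,,,,,,
2,0.024243,,,,,,,,
3,0.018609,0.004956,,,,,,,
4,0.014866,0.003252,0.004825,,,,,,
5,0.012592,0.002072,0.003172,0.004541,,,,,
6,0.011161,0.001362,0.002024,0.002990,0.004325,,,,
7,0.010173,0.000956,0.001333,0.001911,0.002853,0.004169,,,
8,0.009429,0.000678,0.000937,0.001260,0.001826,0.002754,0.004065,,
9,0.008853,0.000495,0.000666,0.000887,0.001207,0.001766,0.002690,0.003982,
10,0.008310,0.000459,0.000487,0.000632,0.000851,0.001169,0.001728,0.002639,0.003912
11,,,0.000452,0.000463,0.000607,0.000826,0.001146,0.001698,0.002597
12,,,,0.000430,0.000445,0.000590,0.000811,0.001127,0.001674
13,,,,,0.000415,0.000434,0.000580,0.000799,0.001113
14,,,,,,0.000404,0.000426,0.000572,0.000789
15,,,,,,,0.000397,0.000420,0.000564
16,,,,,,,,0.000391,0.000414
17,,,,,,,,,0.000385
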