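month,parity_le2,parity_ge3
1,1252,1025
2,1228,1333
3,1187,1332
4,1129,1264
5,1103,1181
6,935,1025
7,969,1076
8,868,920
9,827,858
10,703,719
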