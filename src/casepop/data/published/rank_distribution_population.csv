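rank,share
1,30.37
2,23.58
3,16.09
4,10.68
5,7.07
6,4.74
7,3.16
8,2.10
9,2.22
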