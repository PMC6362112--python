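rank,share
1,43.51
2,28.55
3,14.63
4,6.89
5,3.2
6,1.65
7,0.81
8,0.43
9,0.34
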