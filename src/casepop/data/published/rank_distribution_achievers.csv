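rank,share
1,48.15
2,25.69
3,14.1
4,6.15
5,3.28
6,1.18
7,0.77
8,0.26
9,0.41
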