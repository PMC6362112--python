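father_band,share
<25,6.3
25-29,28.6
30-34,27.7
35-39,19.3
40-44,11.1
45-49,4.9
>=50,2.1
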