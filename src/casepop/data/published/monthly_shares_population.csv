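year,m01,m02,m03,m04,m05,m06,m07,m08,m09,m10,m11,m12
1896,8.67,8.33,9.17,8.75,8.58,8.08,8.33,8.25,8,7.92,7.75,8
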