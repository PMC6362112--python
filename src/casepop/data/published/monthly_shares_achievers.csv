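year,m01,m02,m03,m04,m05,m06,m07,m08,m09,m10,m11,m12
1896,8.91,7.23,8.87,8.51,9.05,8.03,8.56,8.34,8.2,9.71,7.18,7.41
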