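factor,n_exposed,n_total,pct_printed
urbanicity,1303,1546,84.28
paternal_age,473,1330,35.56
migration,145,1742,7.68
first_born,295,1972,48.15
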