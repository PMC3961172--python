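stratum,n_neither,n_maternal_only,n_paternal_only,n_both
<30,500,66,64,13
30-34,1313,177,167,20
35-39,3089,339,297,45
40-44,4925,569,476,78
45-49,6135,660,520,68
50-54,4940,484,373,49
55-59,3510,229,228,22
60-89,3151,203,195,24
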