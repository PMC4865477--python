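site,crop_1500,wet_250,large_trail,crop_edge
s1,0.42,0.05,1,0
s2,0.13,0.22,0,0
s3,0.55,0.01,1,1
s4,0.08,0.40,0,0
s5,0.31,0.18,0,1
s6,0.25,0.09,1,0
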