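site,array,active_1,active_2,active_3
s1,north,1,1,1
s2,north,1,0,1
s3,north,1,1,1
s4,south,1,1,1
s5,south,1,1,0
s6,south,1,1,1
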