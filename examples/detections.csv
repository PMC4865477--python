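species,site,occasion,detected
coyote,s1,1,1
coyote,s1,3,1
coyote,s2,1,0
coyote,s3,2,1
coyote,s4,1,0
coyote,s6,2,1
red_fox,s1,1,0
red_fox,s3,1,1
red_fox,s3,2,1
red_fox,s5,1,0
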