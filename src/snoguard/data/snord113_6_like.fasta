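>SNORD113-6-like-synthetic synthetic reconstruction of a C/D-box snoRNA; not a database sequence
GGACAUGAUGAUCAUCCCUGGGGUUACUGAACGUACGUACGUACGUACGUGCCAAUCGGC
UGAGUCCU
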