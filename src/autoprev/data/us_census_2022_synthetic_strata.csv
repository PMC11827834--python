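sex,age_group,population
female,0-17,35700000
female,18-44,58600000
female,45-64,42300000
female,65+,33100000
male,0-17,37300000
male,18-44,59400000
male,45-64,40200000
male,65+,26700000
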