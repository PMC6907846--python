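cross_ethnicity,incorrect,correct
mismatch,845,1081
match,827,1189
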