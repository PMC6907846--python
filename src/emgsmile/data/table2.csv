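stimulus,incorrect,correct
posed,902,1201
spontaneous,770,1069
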