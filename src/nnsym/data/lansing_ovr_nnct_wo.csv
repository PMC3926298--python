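class,white_oak,rest
white_oak,236,212
rest,167,482
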