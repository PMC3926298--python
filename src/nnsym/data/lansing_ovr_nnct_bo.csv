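class,black_oak,rest
black_oak,53,82
rest,78,884
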