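class,0,1,>=2
black_oak,37,67,31
rest,256,479,227
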