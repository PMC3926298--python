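class,0,1,>=2
black_oak,36,64,35
white_oak,135,203,110
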