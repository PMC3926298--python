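class,0,1,>=2
white_oak,143,219,86
rest,150,327,172
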