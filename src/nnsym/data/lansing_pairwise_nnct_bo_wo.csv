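class,black_oak,white_oak
black_oak,78,67
white_oak,72,376
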