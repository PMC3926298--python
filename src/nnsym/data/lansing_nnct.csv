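class,black_oak,maple,white_oak
black_oak,53,35,47
maple,28,366,120
white_oak,50,161,237
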