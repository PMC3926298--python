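class,0,1,>=2
black_oak,38,65,32
maple,142,242,130
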