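class,black_oak,maple
black_oak,82,53
maple,49,465
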