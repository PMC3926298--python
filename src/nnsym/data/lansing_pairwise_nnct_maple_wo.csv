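class,maple,white_oak
maple,379,135
white_oak,172,276
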