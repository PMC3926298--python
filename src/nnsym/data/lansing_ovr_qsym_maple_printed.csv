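class,0,1,>=2
maple,112,259,148
rest,181,286,116
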