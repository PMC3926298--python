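class,0,1,>=2
maple,117,258,139
white_oak,136,224,88
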