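class,sedentary,active
sedentary,11926,2692
active,1026,13968
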