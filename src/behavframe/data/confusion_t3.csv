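class,sedentary,light,moderate,vigorous
sedentary,13259,4915,323,22
light,197,939,115,14
moderate,1253,2344,6352,60
vigorous,2,83,110,72
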