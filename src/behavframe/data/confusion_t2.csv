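class,sedentary,mixed_movement,walking,running
sedentary,2338,0,283,6
mixed_movement,307,758,381,7
walking,928,0,1166,5
running,2,663,1580,2861
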