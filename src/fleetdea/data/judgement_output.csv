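X5,X6,X7,X8
1,1.3,2.5,1.8
0.769,1,3,2
0.4,0.333,1,0.5
0.555,0.5,2,1
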