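X1,X2,X3,X4
1,2.1,1.5,1.8
0.476,1,0.333,0.5
0.666,3,1,2
0.555,2,0.5,1
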