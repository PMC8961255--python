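group,value
A,0.7450
A,0.7513
A,0.8484
A,0.8584
A,0.8728
A,0.8964
A,0.9053
A,1.0981
B,0.5148
B,0.5280
B,0.5546
B,0.5553
B,0.6265
B,0.6315
B,0.6890
B,0.7605
B,0.7843
B,0.8173
C,0.1088
C,0.1732
C,0.1896
C,0.2202
C,0.2352
C,0.2697
C,0.3298
C,0.4150
C,0.4234
C,0.4401
D,0.0133
D,0.0265
D,0.0302
D,0.0444
D,0.0882
D,0.1461
D,0.1545
D,0.1585
D,0.2638
E,-0.1221
E,-0.1010
E,-0.0519
E,-0.0436
E,-0.0200
E,-0.0182
E,-0.0104
E,0.0879
E,0.1390
E,0.1945
F,-0.1946
F,-0.0520
F,-0.0417
F,-0.0039
F,0.0076
F,0.0196
F,0.0512
F,0.1540
F,0.2247
D',0.4033
D',0.4087
D',0.4103
D',0.4163
D',0.4354
D',0.4624
D',0.4665
D',0.4684
D',0.5232
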