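A,f,phi
1,0.156250,4.95
0.3,0.390625,3.82
0.25,0.859375,4.37
0.25,1.484375,3.67
0.175,2.421875,4.05
0.175,4.609375,4.13
0.125,8.046875,4.02
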