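coefficient,value
a0,1.02772
a1,0.18833
a2,-0.13205
a3,0.0172
a4,-7.31e-4
a5,4.06e-6
R,0.99998
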