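r_mm,mcnp5,egsnrc,fluka
1.0,1.100,1.100,1.108
1.5,1.070,1.070,1.076
2.0,1.000,1.000,1.000
2.5,0.912,0.917,0.905
3.0,0.810,0.816,0.792
3.5,0.703,0.697,0.664
4.0,0.587,0.586,0.548
4.5,0.475,0.475,0.433
5.0,0.374,0.371,0.332
5.5,0.282,0.285,0.251
6.0,0.202,0.201,0.174
6.5,0.137,0.138,0.118
7.0,0.088,0.089,0.075
7.5,0.053,0.055,0.046
8.0,0.030,0.031,0.026
8.5,0.015,0.015,0.013
9.0,0.007,0.007,0.006
9.5,0.003,0.003,0.003
10.0,0.001,0.001,0.001
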