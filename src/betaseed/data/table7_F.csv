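theta_deg,1.0,1.5,2.0,2.5,3.0,3.5,4.0,4.5,5.0,5.5,6.0,6.5,7.0,7.5,8.0,8.5,9.0,9.5,10.0
0,,,,0.856,0.939,0.979,0.955,1.036,1.094,1.162,1.318,1.352,1.645,1.967,2.317,2.774,3.860,5.544,5.886
10,,,,0.948,0.944,0.966,0.998,1.048,1.102,1.189,1.292,1.422,1.623,1.893,2.313,2.901,3.841,5.146,6.785
20,,1.110,1.133,1.007,0.989,1.005,1.033,1.079,1.132,1.205,1.302,1.430,1.607,1.854,2.186,2.728,3.557,4.789,5.982
30,1.051,1.064,1.085,1.048,1.034,1.042,1.066,1.099,1.141,1.202,1.285,1.398,1.545,1.750,2.052,2.505,3.169,4.068,4.906
40,1.021,1.045,1.063,1.055,1.048,1.055,1.071,1.099,1.132,1.180,1.250,1.334,1.455,1.616,1.810,2.117,2.668,3.313,3.914
50,1.011,1.029,1.043,1.043,1.042,1.050,1.061,1.084,1.104,1.145,1.186,1.250,1.328,1.445,1.591,1.805,2.101,2.498,2.790
60,1.006,1.016,1.025,1.027,1.029,1.034,1.041,1.055,1.068,1.093,1.115,1.152,1.196,1.267,1.356,1.484,1.619,1.912,1.920
70,1.003,1.008,1.012,1.011,1.014,1.017,1.021,1.027,1.033,1.043,1.055,1.077,1.096,1.124,1.146,1.225,1.283,1.354,1.411
80,1.001,1.002,1.004,1.003,1.004,1.003,1.005,1.009,1.007,1.010,1.015,1.025,1.025,1.034,1.039,1.056,1.060,1.090,0.949
90,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000
phi_an,1.107,1.345,1.313,1.406,1.277,1.208,1.178,1.167,1.165,1.179,1.205,1.251,1.310,1.399,1.522,1.708,1.987,2.374,2.668
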