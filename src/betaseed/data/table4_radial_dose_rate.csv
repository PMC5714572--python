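r_mm,mcnp5,egsnrc,fluka
1.0,15.1808,14.8252,15.1650
1.5,8.3660,8.1798,8.3662
2.0,5.0542,4.9524,5.0244
2.5,3.2021,3.1369,3.1440
3.0,2.0809,2.0366,2.0120
3.5,1.3742,1.3373,1.2952
4.0,0.9000,0.8799,0.8346
4.5,0.5858,0.5750,0.5326
5.0,0.3784,0.3706,0.3375
5.5,0.2383,0.2331,0.2081
6.0,0.1445,0.1428,0.1256
6.5,0.0844,0.0837,0.0727
7.0,0.0470,0.0468,0.0400
7.5,0.0246,0.0246,0.0211
8.0,0.0121,0.0121,0.0104
8.5,0.0054,0.0055,0.0047
9.0,0.0022,0.0022,0.0019
9.5,0.0008,0.0008,0.0008
10.0,0.0003,0.0003,0.0003
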