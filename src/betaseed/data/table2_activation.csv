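radionuclide,parent_xs_b,half_life,half_life_unit,radiation,yield
90Y,1.28,64.1,h,beta 2.284 MeV,100%
90mY,0.001,3.19,h,gamma 480 keV,90.0%
153Sm,206.00,46.7,h,beta 0.817 MeV; gamma 103 keV,21.0%; 28.3%
31Si,0.107,2.62,h,beta 1.492 MeV; gamma 1.27 MeV,99.9%; 0.07%
28Al,0.231,2.24,m,beta 2.864 MeV; gamma 1.78 MeV,100%; 100%
19O,0.00016,26.9,s,beta 4.819 MeV; gamma 1.36 MeV,56.1%; 50.3%
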