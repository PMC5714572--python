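radionuclide,half_life,half_life_unit,emax_MeV,emax_branch_pct,emean_MeV,parent_abundance_pct,gamma_emissions,parent_xs_b
90Y,64.0,h,2.284,100,0.934,100,Brems,1.28
90Sr,29.1,y,0.546,100,0.196,,Brems,
32P,14.3,d,1.710,100,0.695,100,Brems,0.172
186Re,90.6,h,1.076,73.0,0.350,37.4,137 (8.65%),112
188Re,17.0,h,2.119,71.6,0.764,62.6,155 (14.9%),76.4
153Sm,46.7,h,0.817,21.0,0.228,26.75,103 (28.3%),206
142Pr,19.1,h,2.159,96.3,0.809,100,1580 (3.7%),11.5
177Lu,6.71,d,0.497,78.6,0.133,2.59,208 (11.0%),2090
166Ho,26.8,h,1.856,51.0,0.667,100,80.6 (6.2%),64.7
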