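element,molar_mass_g_mol,activatable_parent,parent_natural_abundance,product
Y,88.90585,89Y,1.0,90Y
O,15.9994,18O,0.00205,19O
Si,28.0855,30Si,0.030925,31Si
Al,26.9815385,27Al,1.0,28Al
152Sm,151.919739,152Sm,1.0,153Sm
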