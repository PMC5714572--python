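element,weight_pct,mass_mg
Y,43.2,3.722
O,34.7,2.994
Si,14.0,1.203
Al,7.9,0.679
152Sm,0.2,0.02
Total,100,8.618
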