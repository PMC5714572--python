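code,dose_rate,uncertainty
MCNP5,5.0542,0.0029
EGSnrc,4.9524,0.0035
FLUKA,5.0244,0.0030
Average,5.0103,0.0018
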