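# constitutive production and first-order degradation of a species
0 -> S ; k=1.0
S -> 0 ; k=1.0
init: S=0
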