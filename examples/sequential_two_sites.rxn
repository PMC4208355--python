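# gene with two TF binding sites occupied in a fixed order
G0 + F -> G1 ; k=1.0
G1 -> G0 + F ; k=1.0
G1 + F -> G2 ; k=1.0
G2 -> G1 + F ; k=1.0
init: F=4 G0=1 G1=0 G2=0
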