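# gene with two TF binding sites occupied in either order (4-state cycle)
G00 + F -> G10 ; k=1.0
G10 -> G00 + F ; k=1.0
G00 + F -> G01 ; k=1.0
G01 -> G00 + F ; k=1.0
G10 + F -> G11 ; k=1.0
G11 -> G10 + F ; k=1.0
G01 + F -> G11 ; k=1.0
G11 -> G01 + F ; k=1.0
init: F=4 G00=1 G10=0 G01=0 G11=0
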