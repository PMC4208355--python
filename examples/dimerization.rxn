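# protein dimerization; note kappa*X*(X-1) convention (no factor 1/2)
2 M -> D ; k=1.0
D -> 2 M ; k=2.0
init: M=9 D=0
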