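# gene regulated by dimer TFs: 2M <-> D, G + D <-> G* (ladder state space)
2 M <-> D ; kf=1.0 ; kr=1.0
G + D <-> Gs ; kf=1.0 ; kr=1.0
init: M=8 D=0 G=1 Gs=0
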