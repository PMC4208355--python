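# one gene, T=4 TFs: Bernoulli equilibrium (Hill coefficient 1)
G + F <-> Gs ; kf=1.5 ; kr=1.0
init: F=4 G=1 Gs=0
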