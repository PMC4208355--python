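# two-conformation molecule pool (also a coarse Goldbeter-Koshland switch)
S1 <-> S2 ; kf=1.0 ; kr=1.0
init: S1=0 S2=10
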