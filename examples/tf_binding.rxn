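# transcription factors binding N=2 gene copies, T=5 TFs
G + F -> Gs ; k=1.0
Gs -> G + F ; k=1.0
init: F=5 G=2 Gs=0
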