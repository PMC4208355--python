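# three TFBSs: a unique site binds the first TF, the other two bind in any order
Ge + F -> Gu ; k=1.0
Gu -> Ge + F ; k=1.0
Gu + F -> GuA ; k=1.0
GuA -> Gu + F ; k=1.0
Gu + F -> GuB ; k=1.0
GuB -> Gu + F ; k=1.0
GuA + F -> GuAB ; k=1.0
GuAB -> GuA + F ; k=1.0
GuB + F -> GuAB ; k=1.0
GuAB -> GuB + F ; k=1.0
init: F=5 Ge=1 Gu=0 GuA=0 GuAB=0 GuB=0
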