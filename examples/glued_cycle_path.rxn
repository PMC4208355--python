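# mirror image: two sites bind the first two TFs in any order, then the unique site
Ge + F -> GA ; k=1.0
GA -> Ge + F ; k=1.0
Ge + F -> GB ; k=1.0
GB -> Ge + F ; k=1.0
GA + F -> GAB ; k=1.0
GAB -> GA + F ; k=1.0
GB + F -> GAB ; k=1.0
GAB -> GB + F ; k=1.0
GAB + F -> GABu ; k=1.0
GABu -> GAB + F ; k=1.0
init: F=5 Ge=1 GA=0 GB=0 GAB=0 GABu=0
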