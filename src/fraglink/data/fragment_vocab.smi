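[*]c1ccccc1
[*]c1ccncc1
[*]c1ccc(F)cc1
[*]c1ccc(OC)cc1
[*]C(=O)c1ccccc1
[*]C(=O)NC
[*]c1ccc(C(N)=O)cc1
[*]c1ccc2ccccc2c1
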