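# linker fragments joining a core to a tail
C
CC
CCC
CN
CO
C(=O)N
C(=O)O
S(=O)(=O)N
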