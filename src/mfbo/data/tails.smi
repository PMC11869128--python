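# terminal fragments for synthetic library assembly
C
CC
CCC
CCCC
C(C)C
C(C)(C)C
CC(C)C
CCN
CCO
CO
CN(C)C
C(F)(F)F
C#N
CC#N
c1ccccc1
c1ccncc1
Cc1ccccc1
c1ccc(F)cc1
CC(=O)C
CCNC
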