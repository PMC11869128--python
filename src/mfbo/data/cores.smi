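# scaffold fragments: appended-to prefixes for synthetic library assembly
c1ccccc1
c1ccncc1
c1cccnc1
c1cncnc1
c1ccc2ccccc2c1
c1ccc2[nH]ccc2c1
c1ccc2occc2c1
c1ccc2sccc2c1
C1CCCCC1
C1CCCC1
C1CCNCC1
C1CCOCC1
c1ccc(F)cc1
c1ccc(Cl)cc1
c1ccc(C)cc1
c1ccc(OC)cc1
c1ccc(C(F)(F)F)cc1
c1csc(C)c1
c1coc(C)c1
C1CN(C)CCN1C
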