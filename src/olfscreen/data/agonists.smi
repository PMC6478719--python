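CC(C)Cc1ccc(O)cc1 A1
Oc1ccc(cc1)C1CCCCC1 A2
CCC(C)Cc1ccc(O)cc1 A3
CC(C)(C)c1ccc(O)cc1 B1
CCCCCc1ccc(O)c(OC)c1 A4
COc1cc(ccc1O)C1CCCC1 A5
C=CCc1ccc(O)c(OC)c1 B2
C/C=C/c1ccc(O)c(OC)c1 B3
CCCc1ccc(O)c(OC)c1 B4
CC(C)Cc1ccc(O)c(OC)c1 B5
CC(C)=CCc1ccc(O)c(OC)c1 B6
C=CCc1cc(OC)c(O)c(OC)c1 B7
COc1cc(ccc1O)C1CCC(C)=CC1 B8
CCOc1ccc(C=O)cc1OC A6
CCOc1cc(C=O)ccc1OC A7
COc1ccc(C=O)c(OC)c1 A8
COc1ccc(C=O)cc1 B9
COc1ccc(C=O)cc1OC B10
CCOc1ccc(C=O)cc1 B11
COc1cc(C=O)cc(OC)c1OC B12
Cc1cc(C=O)ccc1OC B13
CCC(=O)c1ccc(O)cc1 A9
COc1cc(C(C)=O)cc(OC)c1O A10
CC(=O)c1ccc(O)cc1 A11
O=Cc1ccc(O)cc1 A12
COc1ccc(C=O)cc1O A13
COc1cc(O)ccc1C=O A14
COc1ccc(O)c(C=O)c1 A15
COc1cc(C=O)ccc1O B14
CCOc1cc(C=O)ccc1O B15
COc1cc(C(C)=O)ccc1O B16
COc1cc(CCC(C)=O)ccc1O B17
COc1cc(C=O)cc(OC)c1O B18
COc1cc(CO)ccc1O B19
COc1cccc(C=O)c1O B20
CC(=O)c1ccc(O)c(C)c1 B21
CC(=O)CCc1ccc(O)cc1 B22
CCCC1CCC(=O)CC1 A16
CC(C)C1CCC(=O)CC1 A17
CC(C)(C)C1CCC(=O)CC1 B23
CCC(C)C1CCC(=O)CC1 B24
CC1CCOC(C1)/C=C(C)/C B25
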