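# Small library of real, chemically valid SMILES used to label synthetic
# drugs so fingerprint featurization is exercised end-to-end.
CC(=O)Oc1ccccc1C(=O)O
Cn1cnc2c1c(=O)n(C)c(=O)n2C
CC(C)Cc1ccc(cc1)C(C)C(=O)O
CC(=O)Nc1ccc(O)cc1
Clc1ccccc1C(=O)O
OC(=O)c1ccccc1O
Nc1ccc(cc1)S(=O)(=O)N
CN1CCC[C@H]1c1cccnc1
OCC(O)CO
NC(=O)c1ccccc1
Oc1ccc(cc1)CCN
CCN(CC)CCNC(=O)c1ccc(N)cc1
COc1ccc2cc(ccc2c1)C(C)C(=O)O
CC(C)NCC(O)c1ccc(O)c(O)c1
CN(C)CCc1c[nH]c2ccccc12
Oc1ccc2[nH]cc(CCN)c2c1
NC(Cc1ccc(O)cc1)C(=O)O
NC(Cc1c[nH]c2ccccc12)C(=O)O
CC(N)Cc1ccccc1
CNC(C)Cc1ccccc1
OC(=O)CCc1ccccc1
COc1cc2c(cc1OC)C(=O)C(CC2)Cc1ccn(C)c1
CCOC(=O)c1ccccc1N
Cc1ccccc1N
Oc1ccccc1
c1ccc2ccccc2c1
c1ccc(cc1)c1ccccc1
Clc1ccc(Cl)cc1
Brc1ccccc1
Ic1ccccc1
Fc1ccc(F)cc1
OCCO
OCCN
CC(O)CO
CC(C)O
CCCCCCCCO
CC(C)(C)O
CCOCC
CC(=O)C
CCC(=O)CC
O=C1CCCCC1
C1CCOC1
C1CCNCC1
C1CCNC1
N1CCOCC1
CN1CCNCC1
C1CCCCC1
CC1CCCCC1
C1CC1
C1CCC1
CC(C)C
CCCCCC
C=CC=C
CC=CC
C#CC
CC#N
CCOC(=O)C
CC(=O)OC
CCNCC
CCN(CC)CC
NCCCN
NCCCCN
OC(=O)CCCCC(=O)O
OC(=O)C=CC(=O)O
OC(=O)C(O)C(O)C(=O)O
OCC1OC(O)C(O)C(O)C1O
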