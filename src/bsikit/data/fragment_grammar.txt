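# Fragment grammar for smiles-mode synthetic universes.
# Scaffolds carry one {R} attachment point; compounds are formed by the
# Cartesian product scaffold x substituent and validated with RDKit.

[scaffolds]
c1ccc({R})cc1
c1ccc2cc({R})ccc2c1
c1ccnc({R})c1
c1ccc({R})nc1
c1cnc({R})nc1
c1cc({R})ncn1
c1cc({R})oc1
c1cc({R})sc1
c1cc({R})[nH]c1
c1nc({R})c[nH]1
c1csc({R})n1
c1coc({R})n1
c1ccc2[nH]c({R})cc2c1
c1ccc2oc({R})cc2c1
c1ccc2sc({R})cc2c1
c1ccc2nc({R})ccc2c1
c1ccc2c(c1)cnc({R})c2
c1ccc2c(c1)nc({R})[nH]2
c1ccc2c(c1)oc({R})n2
c1ccc2c(c1)sc({R})n2
C1CCN({R})CC1
C1CN({R})CCN1C
O1CCN({R})CC1
C1CCN({R})C1
C1CCC({R})CC1
C1CCC({R})C1
O1CCC({R})C1
O1CCC({R})CC1
S1CCC({R})CC1
C1CC({R})C1
c1ccc(-c2ccc({R})cc2)cc1
c1ccc(Cc2ccc({R})cc2)cc1
c1ccc(Oc2ccc({R})cc2)cc1
c1ccc(Sc2ccc({R})cc2)cc1
c1ccc(N({R})c2ccccc2)cc1
O=C(c1ccccc1)N({R})C
O=C(N({R})C)c1ccncc1
O=S(=O)(c1ccccc1)N({R})C
c1ccc(C(=O)O{R})cc1
c1ccc(C#Cc2ccc({R})cc2)cc1
c1ccc(/C=C/c2ccc({R})cc2)cc1
c1ccc2c(c1)CCN({R})C2
c1ccc2c(c1)CCC({R})C2
c1ccc2c(c1)OCO2
c1cc2cccc3c2c(c1)CC({R})C3
c1cnc2[nH]cc({R})c2c1
c1cnc2nc({R})ccc2c1
c1cc({R})cc2c1OCCO2
C1CN(c2ccc({R})cc2)CCN1
O=c1[nH]c({R})cc(=O)n1C
O=c1cc({R})occ1
c1cc(-c2cc({R})on2)ccc1
c1cc(-c2nc({R})no2)ccc1
c1ccc(-n2cc({R})cn2)cc1
c1ccc(-n2cc({R})nn2)cc1
N#Cc1ccc({R})cc1

[substituents]
C
CC
CCC
CCCC
C(C)C
C(C)(C)C
CO
CCO
CCCO
OC
OCC
OCCC
N
NC
NCC
N(C)C
CN(C)C
CCN(C)C
F
Cl
Br
C(F)(F)F
OC(F)(F)F
C#N
C(=O)C
C(=O)OC
C(=O)NC
S(C)(=O)=O
SC
CC(=O)NC
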