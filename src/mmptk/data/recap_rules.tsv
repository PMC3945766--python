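# Retrosynthetic bond rules for RECAP-style fragmentation.
# Columns: rule_id <tab> SMARTS <tab> enabled <tab> bond_order
# The two atom-mapped atoms (:1 and :2) define the cleavable bond; it must
# be acyclic in the molecule at application time.  Edit or extend freely;
# pass an alternative file with --rules.
amide	[CX3;$(C=O):1](=O)[NX3;!$(N=*):2]	true	1
ester	[CX3;$(C=O):1](=O)[OX2;$(O[#6]):2]	true	1
amine	[NX3;!$(N=*);!$(N[CX3]=[O,N,S]);!$(N[SX4](=O)=O);!$(N~[!#6;!#1]):1][CX4:2]	true	1
urea	[NX3;$(NC(=O)[NX3]):1][CX3;$(C(=O)[NX3])!$(C(=O)[OX2]):2]	true	1
ether	[OX2;!$(OC=O);!$(O[#6]=*);$([OX2]([#6])[#6]):1][CX4:2]	true	1
olefin	[CX3:1]=[CX3:2]	false	2
quaternary_nitrogen	[NX4+:1][CX4:2]	true	1
aromatic_nitrogen_aliphatic_carbon	[n:1][CX4:2]	true	1
lactam_nitrogen_aliphatic_carbon	[NX3;R;$(N[CX3]=O):1][CX4;!R:2]	true	1
aromatic_carbon_aromatic_carbon	[c:1]-[c:2]	true	1
sulfonamide	[NX3;!$(N=*):1][SX4;$(S(=O)(=O)):2]	true	1
ext_carbamate	[OX2;$(O[#6]):1][CX3;$(C(=O)[NX3]):2]	false	1
ext_thioether	[SX2;$(S([#6])[#6]):1][CX4:2]	false	1
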