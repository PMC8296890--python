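alert_id,smarts,description,family,source
n_benzene,[#7]c1ccccc1,benzene ring with nitrogen-containing substituent,n_benzene,builtin
n_benzene_no_nh,[#7;H0]c1ccccc1,benzene ring with nitrogen-containing substituent (no N-H bond),n_benzene,builtin
alkene,[CX3]=[CX3],alkenes,,builtin
benzyl_halide,"[F,Cl,Br,I][CX4]c1ccccc1",methylbenzene with halogenation at the methyl group,,builtin
n_benzene_one_nh,[#7;H1]c1ccccc1,benzene ring with nitrogen-containing substituent (one N-H bond),n_benzene,builtin
methoxy_methyl_arene,[CH3][OX2]c1ccc([CH3])cc1,methoxy and methyl group with three aromatic carbon bonds in between,,builtin
phenol,[OX2H]c1ccccc1,benzene ring with hydroxyl group,,builtin
halogenated_carbon,"[CX4][F,Cl,Br,I]",halogenated carbon,,builtin
methyl_os_arene,"[CH3]c1ccccc1[#8,#16]",aromatic carbon bond with methyl and O/S groups,,builtin
methoxy_benzene,[CH3][OX2]c1ccccc1,benzene ring with methoxy group-containing substituent,,builtin
n_benzene_two_nh,[NX3;H2]c1ccccc1,benzene ring with nitrogen-containing substituent (two N-H bond),n_benzene,builtin
nitrogen_compound,[#7],nitrogen-containing compound,decomposed,builtin
benzene_ring,c1ccccc1,benzene,decomposed,builtin
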