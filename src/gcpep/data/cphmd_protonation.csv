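peptide,environment,residue,pH,fraction,sd
MP1,solution,Asp2,5.5,0.0061,0.0005
MP1,solution,Asp2,6.5,0.0006,0.0000
MP1,solution,Asp2,7.4,0.0001,0.0000
MP1,solution,Lys4,5.5,1.0000,0.0000
MP1,solution,Lys4,6.5,1.0000,0.0000
MP1,solution,Lys4,7.4,1.0000,0.0000
MP1,solution,Lys5,5.5,1.0000,0.0000
MP1,solution,Lys5,6.5,1.0000,0.0000
MP1,solution,Lys5,7.4,1.0000,0.0000
MP1,solution,Asp8,5.5,0.0035,0.0003
MP1,solution,Asp8,6.5,0.0004,0.0000
MP1,solution,Asp8,7.4,0.0000,0.0000
MP1,solution,Lys11,5.5,1.0000,0.0000
MP1,solution,Lys11,6.5,1.0000,0.0000
MP1,solution,Lys11,7.4,1.0000,0.0000
MP1,adsorbed,Asp2,5.5,0.5363,0.0018
MP1,adsorbed,Asp2,6.5,0.0292,0.0003
MP1,adsorbed,Asp2,7.4,0.0022,0.0000
MP1,adsorbed,Lys4,5.5,1.0000,0.0000
MP1,adsorbed,Lys4,6.5,1.0000,0.0000
MP1,adsorbed,Lys4,7.4,1.0000,0.0000
MP1,adsorbed,Lys5,5.5,1.0000,0.0000
MP1,adsorbed,Lys5,6.5,1.0000,0.0000
MP1,adsorbed,Lys5,7.4,1.0000,0.0000
MP1,adsorbed,Asp8,5.5,0.6350,0.0016
MP1,adsorbed,Asp8,6.5,0.0582,0.0004
MP1,adsorbed,Asp8,7.4,0.0062,0.0001
MP1,adsorbed,Lys11,5.5,1.0000,0.0000
MP1,adsorbed,Lys11,6.5,1.0000,0.0000
MP1,adsorbed,Lys11,7.4,1.0000,0.0000
H-MP1,solution,Asp2,5.5,0.0030,0.0003
H-MP1,solution,Asp2,6.5,0.0003,0.0001
H-MP1,solution,Asp2,7.4,0.0000,0.0000
H-MP1,solution,His4,5.5,0.4690,0.0029
H-MP1,solution,His4,6.5,0.1204,0.0015
H-MP1,solution,His4,7.4,0.0213,0.0004
H-MP1,solution,His5,5.5,0.7410,0.0023
H-MP1,solution,His5,6.5,0.2952,0.0023
H-MP1,solution,His5,7.4,0.0566,0.0008
H-MP1,solution,Asp8,5.5,0.0179,0.0008
H-MP1,solution,Asp8,6.5,0.0092,0.0005
H-MP1,solution,Asp8,7.4,0.0023,0.0001
H-MP1,solution,His11,5.5,0.8804,0.0015
H-MP1,solution,His11,6.5,0.4499,0.0026
H-MP1,solution,His11,7.4,0.0988,0.0011
H-MP1,adsorbed,Asp2,5.5,0.5646,0.0015
H-MP1,adsorbed,Asp2,6.5,0.1593,0.0009
H-MP1,adsorbed,Asp2,7.4,0.0243,0.0002
H-MP1,adsorbed,His4,5.5,0.9999,0.0000
H-MP1,adsorbed,His4,6.5,0.9981,0.0001
H-MP1,adsorbed,His4,7.4,0.9536,0.0008
H-MP1,adsorbed,His5,5.5,0.9982,0.0001
H-MP1,adsorbed,His5,6.5,0.9951,0.0001
H-MP1,adsorbed,His5,7.4,0.9346,0.0010
H-MP1,adsorbed,Asp8,5.5,0.7536,0.0012
H-MP1,adsorbed,Asp8,6.5,0.3015,0.0013
H-MP1,adsorbed,Asp8,7.4,0.0506,0.0003
H-MP1,adsorbed,His11,5.5,0.9999,0.0000
H-MP1,adsorbed,His11,6.5,0.9963,0.0001
H-MP1,adsorbed,His11,7.4,0.9415,0.0009
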