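id,cas,name,smiles,ec50_mM,observed_class_printed,predicted_class_lda,predicted_ec50_pls,split,glide_energy_kcal_mol
C1,375-22-4,Perfluorobutanoic acid (PFBA),OC(=O)C(F)(F)C(F)(F)C(F)(F)F,2.61,L,L,2.87,train,-19.583
C2,2706-90-3,Perfluoropentanoic acid (PFPeA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,2.14,L,L,2.09,train,-21.171
C3,307-24-4,Perfluorohexanoic acid (PFHxA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.40,L,L,1.41,train,-20.473
C4,375-85-9,Perfluoroheptanoic acid (PFHpA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.68,H,H,0.55,train,-31.114
C5,335-67-1,Perfluorooctanoic acid (PFOA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.84,H,H,0.78,test,-33.059
C6,375-95-1,Perfluorononanoic acid (PFNA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.60,H,H,1.10,train,-37.045
C7,335-76-2,Perfluorodecanoic acid (PFDA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.11,H,H,1.42,test,-40.381
C8,2058-94-8,Perfluoroundecanoic acid (PFUnDA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.49,H,H,1.68,train,-35.144
C9,307-55-1,Perfluorododecanoic acid (PFDoA),OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,2.51,L,L,1.83,train,-25.948
C10,356-02-5,3:3 Fluorotelomer carboxylic acid (3:3 FTCA),OC(=O)CCC(F)(F)C(F)(F)C(F)(F)F,2.06,L,L,2.21,train,-22.287
C11,914637-49-3,5:3 Fluorotelomer carboxylic acid (5:3 FTCA),OC(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.48,H,H,1.04,train,-25.859
C12,27854-30-4,6:3 Fluorotelomer carboxylic acid (6:3 FTCA),OC(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.84,H,H,0.95,train,-27.848
C13,34598-33-9,8:3 Fluorotelomer carboxylic acid (8:3 FTCA),OC(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.16,H,H,1.38,train,-29.169
E1,3330-15-2,"Heptafluoropropyl 1,2,2,2-tetrafluoroethyl ether",FC(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)F,2.34,L,L,2.11,test,-18.76
E2,13252-13-6,"2,3,3,3-Tetrafluoro-2-(heptafluoropropoxy)propanoic acid (HFPO-DA)",OC(=O)C(F)(OC(F)(F)C(F)(F)C(F)(F)F)C(F)(F)F,1.83,L,L,1.75,train,-24.764
E3,749836-20-2,"7H-Perfluoro-4-methyl-3,6-dioxaoctanesulfonic acid (Nafion BP2)",OS(=O)(=O)C(F)(F)C(F)(F)OC(F)(C(F)(F)F)C(F)(F)OC(F)C(F)(F)F,1.90,L,L,1.70,train,-27.534
E4,151772-59-7,"Perfluoro-3,6,9-trioxadecanoic acid (PFO3DoDA)",OC(=O)C(F)(F)OC(F)(F)C(F)(F)OC(F)(F)C(F)(F)OC(F)(F)F,1.67,L,L,1.66,test,-34.337
S1,375-73-5,Perfluorobutanesulfonic acid (PFBS),OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.72,L,L,1.79,test,-26.738
S2,355-46-4,Perfluorohexanesulfonic acid (PFHxS),OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.98,H,H,0.92,test,-27.822
S3,1763-23-1,Perfluorooctanesulfonic acid (PFOS),OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.13,H,H,1.12,test,-31.682
S4,757124-72-4,4:2 Fluorotelomer sulfonic acid (4:2 FTSA),OS(=O)(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,1.45,H,L,1.16,train,-23.829
S5,59587-38-1,6:2 Fluorotelomer sulfonic acid (6:2 FTSA),OS(=O)(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,0.47,H,H,0.91,train,-28.131
O1,2043-47-2,4:2 Fluorotelomer alcohol (4:2 FTOH),OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,L,L,,train,-16.373
O2,647-42-7,6:2 Fluorotelomer alcohol (6:2 FTOH),OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,L,L,,test,-21.834
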