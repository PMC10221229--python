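cluster,reference_id,name,smiles
SOM16-Cl-2,V,Vanillyl isobutyrate,CC(C)C(=O)OCc1ccc(O)c(OC)c1
SOM16-Cl-2,V,Vanillin propylene glycol acetal,CC1COC(c2ccc(O)c(OC)c2)O1
SOM16-Cl-2,V,Ethyl vanillin isobutyrate,CCOc1cc(C=O)ccc1OC(=O)C(C)C
SOM16-Cl-2,V,1-Ethoxy-2-methoxybenzene,CCOc1ccccc1OC
SOM16-Cl-2,V,ortho-Dimethyl hydroquinone,COc1ccccc1OC
SOM16-Cl-2,V,Ethyl vanillin,CCOc1cc(C=O)ccc1O
SOM16-Cl-2,V,Vanillyl acetate,CC(=O)OCc1ccc(O)c(OC)c1
SOM16-Cl-2,V,Vanillylidene acetone,COc1cc(/C=C/C(C)=O)ccc1O
SOM16-Cl-2,V,Vanillin hexylene glycol acetal,CC1CC(C)(C)OC(c2ccc(O)c(OC)c2)O1
SOM16-Cl-2,V,Ethyl vanillin hexylene glycol acetal,CCOc1cc(C2OC(C)CC(C)(C)O2)ccc1O
SOM16-Cl-2,V,Ethyl vanillin propylene glycol acetal,CCOc1cc(C2OCC(C)O2)ccc1O
SOM16-Cl-4,WL,7-Methyltetrahydronaphthalenone,Cc1ccc2c(c1)C(=O)CCC2
SOM16-Cl-4,WL,delta-Heptalactone,CCC1CCCC(=O)O1
SOM16-Cl-4,WL,Menthofurolactone,CC1CCC2=C(C)C(=O)OC2C1
SOM16-Cl-4,WL,Octahydrocoumarin,O=C1CCC2CCCCC2O1
SOM16-Cl-4,WL,Laitone,CCCCC1(CCCC)CC(=O)O1
SOM16-Cl-4,WL,Coconut naphthalenone,O=C1CCCC2CCCCC12
SOM16-Cl-4,WL,(R)-Tonka furanone,CCC1OC(=O)C(O)=C1C
SOM16-Cl-4,WL,Dihydromint lactone,CC1CCC2C(C)C(=O)OC2C1
SOM16-Cl-5,F,Anisyl isobutyrate,CC(C)C(=O)OCc1ccc(OC)cc1
SOM16-Cl-5,F,4-Hydroxyphenethyl alcohol,OCCc1ccc(O)cc1
SOM16-Cl-5,F,4-(para-Tolyl)-2-butanone,CC(=O)CCc1ccc(C)cc1
SOM16-Cl-5,F,Tufurol acetate,CC(=O)OCC1CCCO1
SOM16-Cl-5,F,2-Methylbenzyl acetate,CC(=O)OCc1ccccc1C
SOM16-Cl-5,F,alpha-Methylbenzyl propionate,CCC(=O)OC(C)c1ccccc1
SOM16-Cl-5,F,Phenethyl 2-methylbutyrate,CCC(C)C(=O)OCCc1ccccc1
SOM16-Cl-5,F,Methyl 4-phenylbutyrate,COC(=O)CCCc1ccccc1
SOM16-Cl-5,F,Benzyl acetoacetate,CC(=O)CC(=O)OCc1ccccc1
SOM16-Cl-8,bI,beta-Ionyl acetate,CC(OC(C)=O)/C=C/C1=C(C)CCCC1(C)C
SOM16-Cl-8,bI,alpha-Ionol,CC(O)/C=C/C1C(C)=CCCC1(C)C
SOM16-Cl-8,bI,alpha-Ionyl acetate,CC(OC(C)=O)/C=C/C1C(C)=CCCC1(C)C
SOM16-Cl-8,bI,3-Methylcyclohexyl acetate,CC(=O)OC1CCCC(C)C1
SOM16-Cl-8,bI,beta-Irone,CC(=O)/C=C/C1=C(C)CC(C)CC1(C)C
SOM16-Cl-8,bI,Campholene acetate,CC1=CCC(CCOC(C)=O)C1(C)C
SOM16-Cl-8,bI,Nopyl acetate,CC(=O)OCCC1=CCC2CC1C2(C)C
SOM16-Cl-8,bI,4-Dimethyl ionone,CC(=O)C(C)=CC1=C(C)CCCC1(C)C
SOM16-Cl-8,bD,Plum damascone,C/C=C/C(=O)C1C(C)=CCCC1(C)C
SOM16-Cl-8,bD,(Z)-alpha-Damascone,C/C=C\C(=O)C1C(C)=CCCC1(C)C
SOM16-Cl-8,bD,Cyclohexylethyl isovalerate,CC(C)CC(=O)OCCC1CCCCC1
SOM16-Cl-8,bD,Cyclohexylethyl valerate,CCCCC(=O)OCCC1CCCCC1
SOM16-Cl-8,bD,1-(3-(Methylthio)butyryl)-2:6:6-trimethylcyclohexene,CSC(C)CC(=O)C1=C(C)CCCC1(C)C
SOM16-Cl-8,bD,Methyl 2:6:6-trimethyl-3-cyclohexene-1-carboxylate,COC(=O)C1C(C)C=CCC1(C)C
SOM16-Cl-13,IA,2-Methylbutyl butyrate,CCCC(=O)OCC(C)CC
SOM16-Cl-13,IA,Hexyl acetate,CCCCCCOC(C)=O
SOM16-Cl-13,IA,Isobutyl propionate,CCC(=O)OCC(C)C
SOM16-Cl-13,IA,Methyl butyrate,CCCC(=O)OC
SOM16-Cl-13,IA,Isopropyl propionate,CCC(=O)OC(C)C
SOM16-Cl-13,IA,Methyl 4-methylvalerate,CC(C)CCC(=O)OC
SOM16-Cl-13,IA,Isoamyl butyrate,CCCC(=O)OCCC(C)C
SOM16-Cl-13,IA,Propyl acetate,CCCOC(C)=O
SOM16-Cl-13,IA,Butyl acetate,CCCCOC(C)=O
SOM16-Cl-13,IA,Amyl acetate,CCCCCOC(C)=O
SOM16-Cl-14,EA,2-Methylbut-2-enyl formate,CC=C(C)COC=O
SOM16-Cl-14,EA,Isobutyl pyruvate,CC(C)COC(=O)C(C)=O
SOM16-Cl-14,EA,Methyl acetate,COC(C)=O
SOM16-Cl-14,EA,Methyl (E)-2-butenoate,C/C=C/C(=O)OC
SOM16-Cl-14,EA,Ethyl 2-methylbutyrate,CCC(C)C(=O)OCC
SOM16-Cl-14,EA,2-Methylbutyl propionate,CCC(=O)OCC(C)CC
SOM16-Cl-14,EA,Isopropyl acetate,CC(C)OC(C)=O
SOM16-Cl-14,EA,Ethyl nitrite,CCON=O
SOM16-Cl-14,EA,Hexyl lactate,CCCCCCOC(=O)C(C)O
SOM16-Cl-14,EA,Methyl 3-hydroxybutyrate,CC(O)CC(=O)OC
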