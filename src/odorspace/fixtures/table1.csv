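id,name,cas,smiles,notes,proportion_rc
V,Vanillin,121-33-5,COc1cc(C=O)ccc1O,Sweet; vanilla; creamy; chocolate,41.8
F,Frambinone,5471-51-2,CC(=O)CCc1ccc(O)cc1,Sweet; berry; raspberry; ripe; floral; fruity,41.8
IA,Isoamyl acetate,123-92-2,CC(C)CCOC(C)=O,Sweet; fruity; banana; solvent; pear,5.0
bI,beta-Ionone,14901-07-6,CC(=O)/C=C/C1=C(C)CCCC1(C)C,Floral; woody; sweet; fruity; berry; tropical; violet; raspberry; dry; powdery orris,4.3
EA,Ethyl acetate,141-78-6,CCOC(C)=O,Ethereal; fruity; sweet; weedy; green; sharp; brandy; winey,4.3
bD,beta-Damascenone,23696-85-7,C/C=C/C(=O)C1=C(C)C=CCC1(C)C,Fruity; floral; apple; plum; tea; rose; tobacco; natural; grape; raspberry; sweet,2.8
WL,Whiskey lactone,39212-23-2,CCCCC1OC(=O)CC1C,Tonka; coumarinic; coconut; toasted; nutty; celery; burnt; woody; lactonic; maple; lovage,
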