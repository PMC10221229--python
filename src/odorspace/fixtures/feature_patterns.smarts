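# Pharmacophore feature perception patterns.
# Format: <kind><TAB><SMARTS><TAB><comment>
# Kinds: A = hydrogen-bond acceptor (point feature at the matched atom).
# Hydrophobic (H) groups and aromatic rings (R) are perceived
# algorithmically (contiguous non-polar carbon groups / ring centroids);
# only acceptors are SMARTS-driven.
A	[OX1]=[#6]	carbonyl oxygen (aldehyde, ketone, ester, lactone, acid)
A	[OX1]=[#7,#16]	N-oxide / S=O oxygen
A	[OX2;$([OX2]([#6])[#6]),$([OX2H1][#6]);!$([OX2][#6]=[OX1])]	ether / hydroxyl oxygen; ester sp3 oxygen handled separately
A	[OX2;$([OX2]([#6])[#6]=[OX1])]	ester / lactone sp3 oxygen
A	[nX2]	aromatic nitrogen with lone pair (pyridine-like)
A	[NX2]=[#6]	imine nitrogen
A	[NX3;H0;!$(N=*);!$(N[#6]=[OX1]);!$(Na)]	tertiary amine nitrogen
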