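code,role,value,count,units,provenance,note
[CX4H],donor,1.20,1,dimensionless,experimental_1to1,aliphatic CH donor (per CH bond)
[CX4H],acceptor,0.60,1,dimensionless,experimental_1to1,aliphatic CH acceptor (per CH bond)
[CX4H]Cl,donor,1.60,1,dimensionless,optimised,CH polarised by an adjacent chlorine (per CH bond)
[CX4H]Cl,acceptor,0.60,1,dimensionless,experimental_1to1,
[cH],donor,1.40,1,dimensionless,optimised,aromatic CH donor
[cH],acceptor,0.70,2,dimensionless,optimised,aromatic CH pi density above and below the ring plane
[c][CX4],acceptor,0.88,2,dimensionless,optimised,alkyl-substituted aromatic carbon pi density (both faces)
[OH2],donor,2.80,2,dimensionless,experimental_1to1,water OH donors
[OH2],acceptor,4.50,2,dimensionless,experimental_1to1,water lone pairs
[OX2H][CX4],donor,2.70,1,dimensionless,experimental_1to1,alcohol OH donor (monomeric solute value)
[OX2H][CX4],acceptor,5.30,1,dimensionless,experimental_1to1,alcohol oxygen first lone pair
[OX2H][CX4],acceptor,3.98,1,dimensionless,optimised,alcohol oxygen second lone pair (reduced)
[OX2]([CX4])[CX4],acceptor,5.30,1,dimensionless,experimental_1to1,ether oxygen first lone pair
[OX2]([CX4])[CX4],acceptor,3.98,1,dimensionless,assumed,ether oxygen second lone pair (reduced-second-site convention)
[OX1]=[CX3],acceptor,5.80,1,dimensionless,experimental_1to1,carbonyl oxygen first lone pair
[OX1]=[CX3],acceptor,3.80,1,dimensionless,optimised,carbonyl oxygen second lone pair
[CX3]=[OX1],acceptor,0.88,2,dimensionless,assumed,carbonyl carbon pi faces (non-polar pi default)
[CX2]#[NX1],acceptor,0.60,4,dimensionless,assumed,nitrile sp carbon pi electrons
[NX1]#[CX2],acceptor,5.15,1,dimensionless,assumed,nitrile nitrogen lone pair (solvent-site value)
Cl[CX4],acceptor,2.30,1,dimensionless,experimental_1to1,chlorine polar lone-pair site
Cl[CX4],donor,1.20,2,dimensionless,experimental_1to1,chlorine non-polar sites (alkane values)
Cl[CX4],acceptor,0.60,2,dimensionless,experimental_1to1,chlorine non-polar sites (alkane values)
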