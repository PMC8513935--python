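member,class,smiles,n_alpha1,n_alpha2,n_beta1,n_beta2
tetrahydrofuran,ethers,C1CCOC1,8,0,8,2
diethyl ether,ethers,CCOCC,10,0,10,2
di-n-butyl ether,ethers,CCCCOCCCC,18,0,18,2
acetonitrile,nitriles,CC#N,0,3,3,5
propionitrile,nitriles,CCC#N,3,2,5,5
butyronitrile,nitriles,CCCC#N,5,2,7,5
acetone,ketones,CC(C)=O,0,6,6,4
butanone,ketones,CCC(C)=O,3,5,8,4
cyclohexanone,ketones,O=C1CCCCC1,6,4,10,4
methanol,alcohols,CO,3,1,3,2
ethanol,alcohols,CCO,5,1,5,2
propan-1-ol,alcohols,CCCO,7,1,7,2
butan-1-ol,alcohols,CCCCO,9,1,9,2
pentan-1-ol,alcohols,CCCCCO,11,1,11,2
hexan-1-ol,alcohols,CCCCCCO,13,1,13,2
heptan-1-ol,alcohols,CCCCCCCO,15,1,15,2
octan-1-ol,alcohols,CCCCCCCCO,17,1,17,2
decan-1-ol,alcohols,CCCCCCCCCCO,21,1,21,2
propan-2-ol,alcohols,CC(C)O,7,1,7,2
butan-2-ol,alcohols,CCC(C)O,9,1,9,2
2-methylpropan-1-ol,alcohols,CC(C)CO,9,1,9,2
2-methylpropan-2-ol,alcohols,CC(C)(C)O,9,1,9,2
3-methylbutan-1-ol,alcohols,CC(C)CCO,11,1,11,2
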