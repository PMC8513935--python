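n_alkyl,beta,units,provenance,note
0,2.00,dimensionless,experimental_1to1,benzene-like ring
1,2.20,dimensionless,experimental_1to1,toluene-like ring
2,2.40,dimensionless,experimental_1to1,xylene-like ring
3,2.70,dimensionless,experimental_1to1,mesitylene-like ring
6,3.10,dimensionless,experimental_1to1,hexamethylbenzene-like ring
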