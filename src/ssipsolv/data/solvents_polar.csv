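class,field,value,units,provenance,note
ethers,alpha_s1,1.20,dimensionless,experimental_1to1,non-polar CH donor (alkane value)
ethers,c_alpha1,2.58,kJ/mol,optimised,
ethers,beta_s1,0.60,dimensionless,experimental_1to1,non-polar CH acceptor (alkane value)
ethers,c_beta1,2.98,kJ/mol,optimised,
ethers,alpha_s2,,dimensionless,fixed,ethers have no polar donor site
ethers,c_alpha2,,kJ/mol,fixed,
ethers,beta_s2,5.30,dimensionless,experimental_1to1,ether oxygen acceptor
ethers,c_beta2,-3.65,kJ/mol,optimised,
ethers,c0,2.26,kJ/mol,optimised,
nitriles,alpha_s1,1.20,dimensionless,experimental_1to1,
nitriles,c_alpha1,-0.79,kJ/mol,optimised,
nitriles,beta_s1,0.60,dimensionless,experimental_1to1,
nitriles,c_beta1,2.69,kJ/mol,optimised,
nitriles,alpha_s2,1.50,dimensionless,experimental_1to1,activated CH donor adjacent to the nitrile
nitriles,c_alpha2,2.67,kJ/mol,optimised,
nitriles,beta_s2,5.15,dimensionless,experimental_1to1,nitrile nitrogen acceptor
nitriles,c_beta2,-3.54,kJ/mol,optimised,
nitriles,c0,3.55,kJ/mol,optimised,
ketones,alpha_s1,1.20,dimensionless,experimental_1to1,
ketones,c_alpha1,-0.78,kJ/mol,optimised,
ketones,beta_s1,0.60,dimensionless,experimental_1to1,
ketones,c_beta1,2.82,kJ/mol,optimised,
ketones,alpha_s2,1.50,dimensionless,experimental_1to1,activated CH donor adjacent to the carbonyl
ketones,c_alpha2,2.71,kJ/mol,optimised,
ketones,beta_s2,5.80,dimensionless,experimental_1to1,carbonyl oxygen acceptor
ketones,c_beta2,-4.09,kJ/mol,optimised,
ketones,c0,1.89,kJ/mol,optimised,
alcohols,alpha_s1,1.20,dimensionless,experimental_1to1,
alcohols,c_alpha1,2.75,kJ/mol,optimised,
alcohols,beta_s1,0.60,dimensionless,experimental_1to1,
alcohols,c_beta1,2.95,kJ/mol,optimised,
alcohols,alpha_s2,3.50,dimensionless,experimental_1to1,self-associated hydroxyl donor in the bulk liquid
alcohols,c_alpha2,-6.02,kJ/mol,optimised,
alcohols,beta_s2,6.90,dimensionless,experimental_1to1,self-associated hydroxyl acceptor in the bulk liquid
alcohols,c_beta2,-6.42,kJ/mol,optimised,
alcohols,c0,0.18,kJ/mol,optimised,
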