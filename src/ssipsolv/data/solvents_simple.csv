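name,field,value,units,provenance,note
water,alpha_s,3.80,dimensionless,optimised,solvent donor polarity fitted to hydrocarbon partition data
water,c_alpha,-0.76,kJ/mol,optimised,
water,beta_s,3.47,dimensionless,optimised,solvent acceptor polarity fitted to hydrocarbon partition data
water,c_beta,-0.76,kJ/mol,optimised,
water,c0,0,kJ/mol,fixed,offset defined to be zero for water
hexadecane,alpha_s,1.20,dimensionless,experimental_1to1,alkane solvent donor from 1:1 complexation
hexadecane,c_alpha,2.64,kJ/mol,experimental_1to1,single-site closure with RT ln[S.S] = +6
hexadecane,beta_s,0.60,dimensionless,experimental_1to1,
hexadecane,c_beta,2.64,kJ/mol,experimental_1to1,
hexadecane,c0,0,kJ/mol,fixed,reference solvent for the C0 offset
benzene,alpha_s,1.40,dimensionless,experimental_1to1,
benzene,c_alpha,2.50,kJ/mol,optimised,
benzene,beta_s,2.00,dimensionless,experimental_1to1,pi-face acceptor
benzene,c_beta,1.09,kJ/mol,optimised,
benzene,c0,0,kJ/mol,fixed,
toluene,alpha_s,1.40,dimensionless,experimental_1to1,
toluene,c_alpha,2.50,kJ/mol,optimised,
toluene,beta_s,2.00,dimensionless,experimental_1to1,
toluene,c_beta,1.09,kJ/mol,optimised,
toluene,c0,0,kJ/mol,fixed,
hexane,alpha_s,1.20,dimensionless,experimental_1to1,
hexane,c_alpha,2.62,kJ/mol,optimised,
hexane,beta_s,0.60,dimensionless,experimental_1to1,
hexane,c_beta,2.62,kJ/mol,optimised,
hexane,c0,1.38,kJ/mol,optimised,
cyclohexane,alpha_s,1.20,dimensionless,experimental_1to1,
cyclohexane,c_alpha,2.61,kJ/mol,optimised,
cyclohexane,beta_s,0.60,dimensionless,experimental_1to1,
cyclohexane,c_beta,2.61,kJ/mol,optimised,
cyclohexane,c0,1.33,kJ/mol,optimised,
carbon tetrachloride,alpha_s,1.40,dimensionless,experimental_1to1,
carbon tetrachloride,c_alpha,2.58,kJ/mol,experimental_1to1,single-site closure with RT ln[S.S] = +6
carbon tetrachloride,beta_s,0.60,dimensionless,experimental_1to1,
carbon tetrachloride,c_beta,2.58,kJ/mol,experimental_1to1,
carbon tetrachloride,c0,1.34,kJ/mol,optimised,
dichloromethane,alpha_s,1.80,dimensionless,experimental_1to1,
dichloromethane,c_alpha,2.16,kJ/mol,optimised,
dichloromethane,beta_s,1.40,dimensionless,experimental_1to1,
dichloromethane,c_beta,1.76,kJ/mol,optimised,
dichloromethane,c0,1.73,kJ/mol,optimised,
chloroform,alpha_s,2.10,dimensionless,experimental_1to1,
chloroform,c_alpha,1.78,kJ/mol,optimised,
chloroform,beta_s,1.30,dimensionless,experimental_1to1,
chloroform,c_beta,2.11,kJ/mol,optimised,
chloroform,c0,0.60,kJ/mol,optimised,
"1,2-dichloroethane",alpha_s,1.70,dimensionless,experimental_1to1,
"1,2-dichloroethane",c_alpha,2.23,kJ/mol,optimised,
"1,2-dichloroethane",beta_s,1.60,dimensionless,experimental_1to1,
"1,2-dichloroethane",c_beta,1.41,kJ/mol,optimised,
"1,2-dichloroethane",c0,1.93,kJ/mol,optimised,
chlorobenzene,alpha_s,1.40,dimensionless,experimental_1to1,
chlorobenzene,c_alpha,2.51,kJ/mol,optimised,
chlorobenzene,beta_s,1.40,dimensionless,experimental_1to1,
chlorobenzene,c_beta,1.71,kJ/mol,optimised,
chlorobenzene,c0,1.48,kJ/mol,optimised,
perfluoroalkane,alpha_s,1.20,dimensionless,experimental_1to1,
perfluoroalkane,c_alpha,2.41,kJ/mol,optimised,
perfluoroalkane,beta_s,0.60,dimensionless,experimental_1to1,
perfluoroalkane,c_beta,2.41,kJ/mol,optimised,
perfluoroalkane,c0,0.81,kJ/mol,optimised,
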