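table,symbol,unit,printed_mean,decimals,printed_n,mean_verified,n_verified
table1,type_i,%,80.31,2,27470,true,true
table1,type_ii,%,14.18,2,27470,true,true
table1,type_iii,%,2.89,2,27470,true,true
table2,root_diameter,cm,2.9,1,,true,false
table2,D1,cm,3.2,1,8071,true,true
table2,D2,cm,2.6,1,2133,true,false
table2,proximal_descending_diameter,cm,2.4,1,,true,false
table2,D3,cm,2.5,1,728,true,false
table3,H,cm,4.06,2,509,true,true
table3,W,cm,7.95,2,509,true,true
table3,hw_ratio,dimensionless,0.51,2,509,true,true
table3,R,cm,12.2,1,4,true,true
table4,L,cm,2.6,1,5,true,true
table5,beta1,deg,10,0,5,true,true
table5,beta2,deg,10,0,4,true,true
table5,beta3,deg,10,0,4,true,true
table6,phi1,cm,1.47,2,706,false,false
table6,phi2,cm,0.97,2,706,true,false
table6,phi3,cm,1.14,2,706,false,false
table6,phib1,cm,2.18,2,301,false,false
table6,phib2,cm,1.07,2,301,true,false
table7,a,cm,7.62,2,472,true,true
table7,d1,cm,1.68,2,483,true,false
table7,d2,cm,3.44,2,483,true,false
table7,d3,cm,2.7,2,104,false,false
table8,alpha1,deg,84.77,2,96,true,false
table8,alpha2,deg,73.31,2,96,true,false
table8,alpha3,deg,69.81,2,96,true,false
table8,alphab1,deg,80,0,1,true,true
table8,alphab2,deg,65,0,1,true,true
table9,C1,mm,2.6,1,605,true,true
table9,C2,mm,3.5,1,605,true,true
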