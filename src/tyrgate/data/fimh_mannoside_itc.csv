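ligand,variant,n,Kd_nM,dH_kJ_mol,dG_printed_kJ_mol,TdS_printed_kJ_mol,rKd_printed,rIC50_printed
AM,WT,1.03,1125,-43.1,-34.0,-9.1,1.0,1.0
AM,Y48A,0.96,2715,-40.6,-31.4,-9.2,2.4,1.4
AM,Y137A,0.98,2735,-39.7,-31.8,-7.9,2.4,1.2
HM,WT,0.98,28.9,-50.3,-43.0,-7.3,1.0,1.0
HM,Y48A,1.02,65.5,-36.8,-41.0,4.2,2.3,1.3
HM,Y137A,1.00,206.4,-30.1,-38.0,7.9,7.1,8.7
BF,WT,1.07,17.7,-45.0,-44.2,-0.8,1.0,1.0
BF,Y48A,1.06,46.5,-42.2,-41.8,-0.4,2.6,0.7
BF,Y137A,1.04,89.7,-35.5,-40.1,4.6,5.1,5.8
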