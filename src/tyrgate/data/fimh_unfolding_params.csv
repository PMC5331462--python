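variant,dG_fold_kJ_mol,dG_fold_err,m_kJ_mol_M,m_err,D_half_printed_M
WT,-50.00,3.07,18.17,1.11,2.75
Y48A,-44.05,2.37,15.95,0.85,2.77
Y137A,-53.71,4.53,19.63,1.64,2.73
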