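pdb,l_pdb,temp_k,delta_h_act_kj_mol,delta_cp_act_kj_mol_k,t_hf_printed_k,delta_cp_printed_kj_mol_k,beta_f_printed
2CRO,65,293.15,40.70,-3.05,310.50,3.50,-0.87
1PGB,56,298.15,16.80,-1.90,306.99,2.94,-0.64
1L63,162,285.15,92.05,-6.84,298.61,9.51,-0.72
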