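pdb,l_pdb,temp_k,delta_h_act_kj_mol,delta_cp_act_kj_mol_k,t_hf_printed_k,delta_cp_printed_kj_mol_k,beta_f_printed
1APS,98,301.15,40.70,-2.57,316.99,5.55,-0.46
1D6O,107,298.15,48.53,-2.80,315.46,6.10,-0.46
1E0G,48,298.15,28.45,-1.76,314.34,2.45,-0.72
1HDN,85,293.15,86.10,-3.22,319.89,4.74,-0.68
2VH7,94,301.15,23.60,-2.48,310.67,5.30,-0.47
3CI2,64,298.00,53.55,-2.05,324.12,3.44,-0.60
1EHB,82,298.15,42.40,-3.60,309.93,4.55,-0.79
1CSP,67,298.15,31.60,-2.70,309.85,3.62,-0.74
1AVZ,57,293.00,43.09,-1.86,316.20,3.00,-0.62
1SHG,57,298.00,37.00,-2.30,314.09,3.00,-0.77
1HCD,118,293.15,57.74,-4.39,306.29,6.79,-0.65
2JMC,77,298.15,45.00,-2.20,318.60,4.24,-0.52
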