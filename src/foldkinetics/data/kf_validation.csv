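pdb,fold_class,ln_kf_tx,t_x_k,ln_kf_t0_observed,ln_kf_t0_predicted_printed,t0_k
1FNF,2S,-2.66,278.15,-0.92,-0.12,298.15
1IMQ,2S,7.09,283.15,7.33,8.69,298.15
1K9Q,2S,8.92,311.15,8.37,8.67,298.15
1K9Q,2S,7.41,351.15,8.37,7.87,298.15
1RFA,2S,4.40,281.15,7.00,6.11,298.15
1SS1,2S,12.41,323.15,12.08,12.07,298.15
1SS1,2S,11.33,283.15,12.08,12.37,298.15
1U4Q,2S,9.48,283.15,11.00,11.56,298.15
2WXC,2S,11.17,283.00,11.73,12.00,298.15
1BNI,N2S,2.07,318.15,2.50,2.31,298.15
1DWR,N2S,1.10,281.15,2.88,3.79,299.15
1NFI,N2S,1.00,288.15,1.76,2.08,298.15
1NFI,N2S,0.62,283.15,1.76,2.60,298.15
1EKG,N2S,2.60,288.15,3.54,3.51,298.15
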