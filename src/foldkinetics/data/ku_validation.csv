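pdb,fold_class,ln_ku_tx,t_x_k,ln_ku_t0_observed,ln_ku_t0_predicted_printed,t0_k
1IMQ,2S,-4.42,283.15,-1.87,-1.79,298.15
1K9Q,2S,10.92,351.15,6.66,6.30,298.15
1K9Q,2S,7.38,311.15,6.66,6.33,298.15
1RFA,2S,-3.10,281.15,-1.17,-0.45,298.15
1SS1,2S,7.40,323.15,3.40,4.20,298.15
1SS1,2S,0.92,283.15,3.40,2.61,298.15
1U4Q,2S,-3.37,298.15,0.26,0.06,298.15
2WXC,2S,6.65,283.00,7.65,7.98,298.15
1BNI,N2S,-3.13,318.15,-10.55,-9.51,298.15
1EKG,N2S,-11.02,288.15,-8.87,-7.42,298.15
1ENH,N2S,10.78,325.30,7.00,6.79,298.15
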