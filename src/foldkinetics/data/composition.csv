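folding_type,alpha,beta,alpha_plus_beta,alpha_beta
2S,24,39,25,1
N2S,10,13,16,13
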