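name,A_N,B_mps,F_max_N,l_CE_opt_m,R_PDE,D_eff_Nspm,source
Piglet gastrocnemius,3.0,0.015,30.0,0.015,0.003,2200,B9
Cat soleus,4.8,0.042,21.0,0.033,0.011,620,B3
Cat tenuissimus,0.05,0.057,0.18,0.032,0.600,4,B19
Rat gastrocnemius,2.68,0.042,13.4,0.013,0.167,386,B30
Rat tibialis anterior,4.3,0.053,4.3,0.027,0.076,162,B19
Frog sartorius,0.18,0.012,0.67,0.031,0.287,72,B19
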