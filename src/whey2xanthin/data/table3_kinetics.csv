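cheese_whey_pct_v_v,X0_g_l,Xm_g_l,mu_per_h,SL0_g_l,mC_g_g_h,Y_XS_g_g,alpha_mg_g,beta_mg_g_h,delta_t_h
3,0.0300,3.5500,0.0421,3.50,0.0027,12.28,1.029,0.0150,2.546
6,0.0320,4.0000,0.0837,3.91,0.0029,13.22,1.294,0.0174,2.582
9,0.0290,5.0500,0.1243,4.06,0.0031,14.82,1.598,0.0198,2.494
12,0.0310,5.2000,0.1518,4.22,0.0034,16.95,1.958,0.0199,2.161
15,0.0350,5.1700,0.1427,4.36,0.0029,14.90,1.607,0.0199,2.055
18,0.0330,4.9700,0.1260,4.58,0.0029,13.31,1.548,0.0192,2.347
21,0.0260,4.6800,0.1074,4.76,0.0028,12.25,1.498,0.01813,2.161
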