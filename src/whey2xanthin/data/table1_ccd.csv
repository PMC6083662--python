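run,yeast_extract_g_l,peptone_g_l,cheese_whey_pct_v_v,ph,bcrx_mg_l,biomass_g_l
1,10,10,10,7.75,14.8140,3.82
2,10,5,10,7.75,17.0450,5.16
3,15,7.5,15,7.0,13.0575,3.69
4,15,7.5,5,7.0,14.0800,3.75
5,15,2.5,15,8.5,13.9652,4.07
6,5,2.5,5,8.5,4.2459,2.67
7,5,2.5,5,7.0,3.3500,2.43
8,10,5,10,7.75,16.7555,5.31
9,5,7.5,15,8.5,12.8590,4.15
10,20,5,10,7.75,13.0005,3.67
11,15,7.5,5,8.5,13.2780,3.23
12,5,2.5,15,7.0,8.6440,2.92
13,5,7.5,15,7.0,12.4416,3.66
14,15,2.5,5,7.0,11.0203,4.07
15,10,5,10,7.75,15.5215,5.21
16,10,0,10,7.75,10.2377,3.88
17,10,5,0,7.75,9.4441,3.45
18,10,5,10,9.25,10.6607,3.46
19,5,7.5,5,7.0,9.1972,3.15
20,10,5,10,7.75,15.9500,5.14
21,5,2.5,15,8.5,10.2473,3.92
22,10,5,10,7.75,15.6593,5.12
23,5,7.5,5,8.5,10.4346,3.17
24,0,5,10,7.75,4.1105,2.64
25,10,5,10,6.25,8.8854,3.05
26,15,2.5,5,8.5,12.4019,3.64
27,15,7.5,15,8.5,13.8017,3.90
28,10,5,20,7.75,15.0266,4.25
29,10,5,10,7.75,15.6155,5.12
30,15,2.5,15,7.0,13.9983,3.95
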