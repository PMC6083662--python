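substrate_pct_v_v,mu_per_h
3,0.0421
6,0.0837
9,0.1243
12,0.1518
15,0.1427
18,0.1260
21,0.1074
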