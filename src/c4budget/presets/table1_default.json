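{
 "name": "table1_default",
 "m": 0.55,
 "n_BS": 0.6,
 "CHL": 475,
 "f_bsCHL": 0.33,
 "f_bsPSI": 0.35,
 "alpha": 0.1,
 "k": 0.005,
 "Phi2LL": 0.8,
 "ratio21": 0.85,
 "H_LET": 3,
 "H_CET": 2,
 "h": 4
}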