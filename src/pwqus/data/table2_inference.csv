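parameter,odds_ratio,std_err,z,p,ci_low,ci_high
ac,41734.12,144309.9,3.08,0.002,47.55,36600000
sos,1.02,0.016,1.33,0.183,0.99,1.05
esd,0.91,0.032,-2.70,0.007,0.85,0.97
esc,1.08,0.48,0.18,0.86,0.46,2.57
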