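histogram_id,f1,f2,f3,f4,f5,gold
h01,0.85,0.1,0.05,0.0,0.0,5.0
h02,0.7,0.2,0.1,0.0,0.0,5.0
h03,0.1,0.2,0.4,0.2,0.1,5.0
h04,0.2,0.2,0.2,0.2,0.2,5.0
h05,0.05,0.25,0.4,0.25,0.05,5.0
h06,0.3,0.3,0.2,0.1,0.1,5.0
h07,0.4,0.1,0.1,0.1,0.3,23.0
h08,0.35,0.15,0.0,0.15,0.35,23.0
h09,0.45,0.05,0.0,0.05,0.45,41.0
h10,0.5,0.0,0.0,0.0,0.5,50.0
h11,0.1,0.35,0.1,0.35,0.1,27.5
h12,0.25,0.1,0.3,0.1,0.25,18.5
h13,0.0,0.45,0.1,0.45,0.0,36.5
h14,0.15,0.2,0.1,0.2,0.35,14.0
h15,0.05,0.4,0.05,0.1,0.4,32.0
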