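period_s,lo_deg_s,hi_deg_s,n
0.3,0.045,7.2,20
1.4,0.053,8.4,20
6.7,0.117,13.333,20
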