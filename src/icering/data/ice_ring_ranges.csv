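# Candidate ice-ring resolution windows, v1.
# Lettered windows around the hexagonal-ice (ice Ih) powder rings, given as
# closed intervals in 1/d^2 (A^-2); d_high/d_low in A are derived.
label,inv_d2_lo,inv_d2_hi
A,0.0640,0.0690
B,0.0733,0.0765
C,0.0838,0.0876
D,0.1370,0.1440
E,0.1950,0.2000
F,0.2310,0.2380
G,0.2600,0.2680
H,0.2790,0.2870
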