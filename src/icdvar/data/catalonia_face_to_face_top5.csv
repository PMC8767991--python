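group,n_2019,n_2020,printed_total,printed_total_pct,printed_iav_pct,printed_variation_index
D50-D89,19912,7285,27197,1.03,-63.41,0.14
F01-F99,89415,39196,128611,4.85,-56.16,0.13
H60-H95,45515,22700,68215,2.57,-50.13,0.13
K00-K95,67589,28439,96028,3.62,-57.92,0.11
Q00-Q99,4668,2439,7107,0.27,-47.75,0.10
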