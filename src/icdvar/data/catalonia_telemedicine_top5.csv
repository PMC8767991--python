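group,n_2019,n_2020,printed_total,printed_total_pct,printed_iav_pct,printed_variation_index,note
Z00-Z99,32146,167318,199464,15.68,420.49,0.19,
R00-R99,27092,101122,128214,10.08,273.25,0.11,
M00-M99,27328,99965,127293,10.01,265.80,0.10,
E00-E89,44155,113508,157663,12.40,157.07,0.10,
A00-B99,4670,167318,71620,5.63,1333.62,0.09,printed 2020 count inconsistent with printed total and change
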