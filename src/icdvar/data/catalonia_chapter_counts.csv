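group,n_2019,n_2020,printed_total,printed_total_pct,printed_iav_pct,printed_variation_index
Z00-Z99,186604,296764,483368,12.32,59.03,0.22
E00-E89,261076,202933,464009,11.83,-22.27,0.11
I00-I99,252555,187701,440256,11.23,-25.68,0.13
M00-M99,224901,180912,405813,10.35,-19.56,0.09
R00-R99,200711,184410,385121,9.82,-8.12,0.03
J00-J99,176405,120669,297074,7.57,-31.60,0.11
F01-F99,109203,105506,214709,5.47,-3.39,0.01
N00-N99,96692,85950,182642,4.66,-11.11,0.02
S00-T88,105135,76910,182045,4.64,-26.85,0.06
L00-L99,89119,75640,164759,4.20,-15.12,0.03
A00-B99,52220,99779,151999,3.88,91.07,0.09
K00-K95,78968,64825,143793,3.67,-17.91,0.03
C00-D49,55201,47709,102910,2.62,-13.57,0.01
H60-H95,47699,33796,81495,2.08,-29.15,0.03
G00-G99,38057,34093,72150,1.84,-10.42,0.01
H00-H59,36837,24973,61810,1.58,-32.21,0.02
D50-D89,25305,20246,45551,1.16,-19.99,0.01
V00-Y99,12481,11178,23659,0.60,-10.44,0.00
Q00-Q99,5493,4541,10034,0.26,-17.33,0.00
O00-O9A,3788,3235,7023,0.18,-14.60,0.00
P00-P96,991,763,1754,0.04,-23.01,0.00
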