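element,mass,vdw_volume,sanderson_en,polarizability
H,1.008,6.709,2.592,0.667
B,10.811,17.875,2.275,3.030
C,12.011,22.449,2.746,1.760
N,14.007,15.599,3.194,1.100
O,15.999,11.494,3.654,0.802
F,18.998,9.203,4.000,0.557
Si,28.086,38.792,2.138,5.380
P,30.974,26.522,2.515,3.630
S,32.060,24.429,2.957,2.900
Cl,35.453,23.228,3.475,2.180
Br,79.904,31.059,3.219,3.050
I,126.904,38.792,2.778,5.350
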