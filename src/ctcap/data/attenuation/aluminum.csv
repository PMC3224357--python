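energy_keV,mu_over_rho_cm2_g,mu_en_over_rho_cm2_g
5,193.4,184.0
6,115.3,110.0
8,50.33,48.50
10,26.23,25.43
15,7.955,7.487
20,3.441,3.094
30,1.128,0.8778
40,0.5685,0.3601
50,0.3681,0.1840
60,0.2778,0.1099
80,0.2018,0.05511
100,0.1704,0.03794
150,0.1378,0.02827
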