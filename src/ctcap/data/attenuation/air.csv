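energy_keV,mu_over_rho_cm2_g,mu_en_over_rho_cm2_g
5,40.27,39.31
6,23.41,22.70
8,9.921,9.446
10,5.120,4.742
15,1.614,1.334
20,0.7779,0.5389
30,0.3538,0.1537
40,0.2485,0.06833
50,0.2080,0.04098
60,0.1875,0.03041
80,0.1662,0.02407
100,0.1541,0.02325
150,0.1356,0.02496
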