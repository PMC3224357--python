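energy_keV,mu_over_rho_cm2_g,mu_en_over_rho_cm2_g
5,194.0,186.0
6,117.0,112.0
8,52.30,50.00
10,28.51,26.80
15,9.032,8.388
20,4.001,3.601
30,1.331,1.070
40,0.6655,0.4507
50,0.4242,0.2336
60,0.3148,0.1400
80,0.2229,0.06896
100,0.1855,0.04585
150,0.1480,0.03183
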