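energy_keV,mu_over_rho_cm2_g,mu_en_over_rho_cm2_g
5,42.58,41.30
6,24.70,23.56
8,10.37,9.915
10,5.329,4.944
15,1.673,1.374
20,0.8096,0.5503
30,0.3756,0.1557
40,0.2683,0.06947
50,0.2269,0.04223
60,0.2059,0.03190
80,0.1837,0.02597
100,0.1707,0.02546
150,0.1505,0.02764
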