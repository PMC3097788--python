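# Mass attenuation coefficients, Plexiglas (PMMA, C5H8O2).
# Standard published photon-attenuation tabulation (NIST grid), total with coherent.
# density_g_cm3 = 1.190
# electron_density_rel_water = 1.156
# columns: energy_keV  mu_over_rho_cm2_g
10	3.357
15	1.101
20	0.5714
30	0.3032
40	0.2350
50	0.2074
60	0.1924
80	0.1751
100	0.1641
150	0.1456
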