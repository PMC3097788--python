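# Mass attenuation coefficients, liquid water.
# Values from the standard published photon-attenuation tabulation (NIST grid),
# total attenuation with coherent scattering, interpolated log-log between rows.
# density_g_cm3 = 1.000
# electron_density_rel_water = 1.000
# columns: energy_keV  mu_over_rho_cm2_g
10	5.329
15	1.673
20	0.8096
30	0.3756
40	0.2683
50	0.2269
60	0.2059
80	0.1837
100	0.1707
150	0.1505
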