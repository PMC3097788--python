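# Mass attenuation coefficients, lead.
# Standard published tabulation (NIST grid). The L-edge structure between 13 and
# 16 keV is not resolved (no grid rows there); the K edge at 88 keV is represented
# by a below/above pair. Density follows the value used for the blocker arithmetic
# (11.3 g/cm3) rather than the handbook 11.35.
# density_g_cm3 = 11.300
# electron_density_rel_water = 8.06
# columns: energy_keV  mu_over_rho_cm2_g
10	130.6
20	86.36
30	30.32
40	14.36
50	8.041
60	5.021
80	2.419
88.0	1.910
88.1	7.683
100	5.549
150	2.014
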