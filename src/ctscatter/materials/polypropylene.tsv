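# Mass attenuation coefficients, polypropylene ((CH2)n; identical stoichiometric
# ratio to polyethylene, so the CH2 elemental mixture rule applies).
# Computed from standard elemental H and C tabulations, w_H=0.1437, w_C=0.8563.
# density_g_cm3 = 0.905
# electron_density_rel_water = 0.930
# columns: energy_keV  mu_over_rho_cm2_g
10	2.087
15	0.7451
20	0.4316
30	0.2707
40	0.2275
50	0.2084
60	0.1970
80	0.1823
100	0.1719
150	0.1534
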