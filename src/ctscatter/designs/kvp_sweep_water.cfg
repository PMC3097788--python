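# kVp sweep for the 215 mm water cylinder at 100 mA, 3 s.
# Expected behaviour: integrated SPR of the central row falls monotonically
# with tube voltage; the scatter profile is mirror-symmetric and two-peaked.

[design]
name = kvp_sweep_water
seed = 0
row = 32
spectrum_bin = 5.0
grid_resolution = 5.0

[setup:water_80kvp]
preset = water215
kvp = 80
tube_current = 100

[setup:water_100kvp]
preset = water215
kvp = 100
tube_current = 100

[setup:water_120kvp]
preset = water215
kvp = 120
tube_current = 100

[setup:water_140kvp]
preset = water215
kvp = 140
tube_current = 100

[assert:spr_falls_with_kvp]
kind = decreasing
series = water_80kvp, water_100kvp, water_120kvp, water_140kvp

[assert:mirror_symmetric]
kind = mirror_symmetry
setup = water_120kvp
tol = 0.01

[assert:two_peaked_scatter]
kind = two_peak
setup = water_120kvp

[assert:recovery_120kvp]
kind = recovery
setup = water_120kvp
scatter_rms_max = 0.05
primary_rms_max = 0.02
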