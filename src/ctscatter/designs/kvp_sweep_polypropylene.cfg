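# kVp sweep for the 300 mm polypropylene cylinder (obese-subject surrogate)
# at 200 mA, 3 s.  Integrated SPR of the central row falls with tube voltage.

[design]
name = kvp_sweep_polypropylene
seed = 0
row = 32
spectrum_bin = 5.0
grid_resolution = 5.0

[setup:pp_80kvp]
preset = polypropylene300
kvp = 80
tube_current = 200

[setup:pp_100kvp]
preset = polypropylene300
kvp = 100
tube_current = 200

[setup:pp_120kvp]
preset = polypropylene300
kvp = 120
tube_current = 200

[setup:pp_140kvp]
preset = polypropylene300
kvp = 140
tube_current = 200

[assert:spr_falls_with_kvp]
kind = decreasing
series = pp_80kvp, pp_100kvp, pp_120kvp, pp_140kvp

[assert:mirror_symmetric]
kind = mirror_symmetry
setup = pp_120kvp
tol = 0.01
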