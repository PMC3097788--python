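# Axial off-centring sweep for the water cylinder at 120 kVp / 100 mA.
# Moving the phantom toward the detector (positive offset, smaller air gap)
# increases the integrated SPR of the central row.

[design]
name = air_gap
seed = 0
row = 32
spectrum_bin = 5.0
grid_resolution = 5.0

[setup:toward_tube_100]
preset = water215
axial_offset = -100
kvp = 120

[setup:toward_tube_50]
preset = water215
axial_offset = -50
kvp = 120

[setup:centred]
preset = water215
axial_offset = 0
kvp = 120

[setup:toward_detector_50]
preset = water215
axial_offset = 50
kvp = 120

[setup:toward_detector_100]
preset = water215
axial_offset = 100
kvp = 120

[assert:spr_rises_toward_detector]
kind = increasing
series = toward_tube_100, toward_tube_50, centred, toward_detector_50, toward_detector_100
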