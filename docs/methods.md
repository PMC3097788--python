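# Methods

This note records the physical model behind `ctscatter`, the numerical
choices, the parameters that matter, and what the simulator does and does
not emulate.

## Scanner model

Third-generation fan-beam geometry with a point source at the origin and a
detector arc of radius `source_to_detector` centred on the source. Channels
sample the fan at equal angles, pitch `fan_angle / n_channels`
(56° / 912 ≈ 0.0614°); the fan centre falls midway between the two central
channels (455/456, 0-based), making the angular grid exactly antisymmetric.
Rows are 0.625 mm bins at isocentre, magnified by `SDD/SID = 950/540` at the
detector. The 24 reference elements are modelled as the 12 outermost
channels at each fan edge; they are carried through every matrix and
included in integrated-SPR sums (the row sum runs over all detectors of a
row). All acquisitions are stationary; no gantry rotation, no helical
motion, no bow-tie filter (the modelled measurements are made without one).

Default distances, counts and angles (540 / 950 / 160 mm, 64 × 912, 56°,
0.625 mm) describe the 64-slice scanner the method was developed on; every
component is parametric in `ScannerGeometry`, and the test suite exercises a
scaled-down instance for speed.

## Beam-stop array and shadow projection

The blocker is a one-dimensional array of lead bars in a plane 160 mm below
the source, bars parallel to the row axis, so one shadow mask applies to all
rows. The source is treated as a point (no focal-spot size is modelled), so
the geometric penumbra is zero; `penumbra_margin` (default 2 channels per
side) exists purely to keep partially covered edge channels and their
neighbours out of both the scatter samples and the total-profile knots.
Channels fully inside a projected bar interval are *shadow core*; the
single partially covered channel at each edge enters the primary model with
a linear mix `f·T + (1−f)` of blocked and open transmission.

Bar shadows use the single-valued lead attenuation of the beam-stop
arithmetic, μ = (μ/ρ)·ρ = 3.32 cm²/g × 11.3 g/cm³ = 37.52 cm⁻¹, giving a
3 mm transmission of exp(−11.255) ≈ 1.29 × 10⁻⁵ (the exponential law;
a slightly different figure sometimes quoted for this arithmetic,
1.24 × 10⁻⁵, is not consistent with these μ and t and is not used).
Everywhere else lead uses its full energy-resolved table.

Bar width and spacing are configuration, not measured constants: the
default layout spreads 20 bars, 2 mm wide, evenly over the central 90% of
the fan width at the blocker plane, leaving open channels between shadows
for total-profile sampling.

## Materials and spectra

Mass-attenuation tables for water, Plexiglas (PMMA), polypropylene, lead,
aluminium and copper ship as plain-text files on a 10–150 keV grid
(standard published values; lead's L-edge fine structure is not resolved
and its K edge is a below/above pair). Interpolation is log–log.

The tube spectrum is a Kramers bremsstrahlung continuum,
φ(E) ∝ (kVp − E)/E per bin, hardened by the inherent filtration stack
(3.25 mm Al + 0.1 mm Cu by default) and normalised to unit sum; 1 keV bins
by default, coarser bins (5–10 keV) for simulation speed. Characteristic
tungsten lines are not modelled: only kVp *trends* are asserted downstream,
and those are driven by the continuum hardening. Tube output follows the
standard heuristic photons ∝ mA · s · kVp²; absolute units are arbitrary
and cancel in every SPR.

## Scatter transport

Single Compton scatter only, by design: it reproduces every qualitative
behaviour the measurement method is asserted on (two-peaked profiles,
size ordering, air-gap effect, kVp trend direction) while keeping a
deterministic oracle tractable. The interaction site is sampled in the
phantom *fill*; the thin wall attenuates both legs but is not a scatter
source. The probability that an interaction scatters (rather than being
absorbed) uses the free-electron approximation
μ_inc(E) ≈ n_e σ_KN(E), divided by the tabulated total μ — adequate above
~20 keV. Coherent (Rayleigh) scatter and multiple scatter are excluded; a
uniform `multiple_scatter_factor` (default 1.0) can scale the scatter field
as a crude surrogate.

**Cone illumination.** The beam is a cone covering all 64 rows. The model
treats it as a continuum of incident fan planes distributed uniformly over
the collimated z-extent, frozen laterally at the phantom-centre depth
(half-width `z_half = detector_half_height × x_c / SDD` ≈ 20 mm; the cone
half-angle is ~2°, so the variation across the phantom is a few mm).
Incident directions are in-plane; an interaction's z-offset is uniform over
±z_half; the exit ray carries the full 3-D direction. Primary rays per row
are treated as in-plane too (the ≤2° obliquity changes path lengths by
<0.1%).

**Monte Carlo engine** (`simulate_scatter_mc`). Photons are stratified
equally over the 912 channel rays. Per photon: energy from the spectrum
bins; one forced interaction along the fill chord with depth from the
truncated exponential (weight × (1 − e^{−μL}) × Compton fraction ×
wall-entry attenuation × blocker factor); then `n_splits = 32` exit
directions sampled from the Klein–Nishina law at weight 1/32 (direction
splitting — plain variance reduction; the estimator stays analog: each
split ray deposits its scattered energy E′, attenuated along its exit path,
at the detector element it geometrically hits, or nowhere). The polar angle
is drawn by inverse CDF **tabulated in cos θ**, where the density (the
cross-section itself) is finite and smooth at both endpoints; tabulating in
θ misrepresents the vanishing sin θ density at 0 and π, which the narrow
detector z-band samples preferentially and which produced a measurable
bias during validation. Per-element standard errors come from the deposit
sum of squares. Fixed seed ⇒ bit-identical output.

**Quadrature engine** (`simulate_scatter_deterministic`) integrates the
identical chain: midpoint steps of `grid_resolution` (default 5 mm) along
each incident chord, exact per-step interaction probability
`e^{−μs₀} − e^{−μs₁}`, all 912 exit channels with exact per-channel angular
widths as seen from the interaction point, and an out-of-plane quadrature
in which the slowly varying factor (Klein–Nishina value, scattered energy,
exit attenuation sec ζ) is interpolated as an even quadratic in ζ — the
detector subtends ≤ ~8° out of plane, over which that factor changes by
well under 1%. Exit-z offsets are resolved on a virtual grid, convolved
exactly with the uniform incident-plane distribution, and re-binned to the
physical rows. The result is the expected value of the MC estimator; the
two agree within 3 standard errors on ≥99% of channels at 10⁶ photons, and
in grand total to ~0.5%. Left-right symmetric configurations run the
incident loop over half the fan and mirror (bit-equivalent to the full
loop; disable with `exploit_symmetry=False`).

## Raw data and calibration

Frames are stored in a small documented little-endian container
(magic `CTRAW001`, 66-byte header, float32 or uint16 payload). The
scanner's proprietary dialect is out of scope; this container carries the
same information (64 × 912 readings plus acquisition metadata). Calibration
is per-element gains plus optional affine compression of readings into the
16-bit integer range, mirroring a DAS that compresses high readings for
file size; `decalibrate` applies the inverse. Round trips are exact for
float32 and within half a quantisation step for uint16.

## Measurement pipeline choices

* **Compensation domain**: the phantom-free frame is subtracted on shadowed
  channels only — its open channels contain full primary flux, which must
  not be subtracted. Clamped at zero.
* **Shadow sample**: the mean over a bar's shadow-core channels, positioned
  at the shadow centre (means, not minima — lower variance under noise).
* **Interpolation**: monotone-preserving piecewise cubic (PCHIP) for both
  the scatter samples and the total-profile gap fill; constant extrapolation
  beyond the outermost knots; negatives clamped. Rationale: a plain cubic
  spline overshoots into negative scatter between low samples.
* **SPR validity floor**: channels with primary below `primary_floor`
  (default 10⁻³) × the row maximum are masked (NaN) and contribute 0 to the
  integrated SPR; this guards against SPR blow-ups behind near-zero primary
  in off-centre cases. A row whose primary is entirely below the floor is a
  degenerate-input error.
* Rows are processed independently; no cross-row smoothing. Internally rows
  and channels are 0-based; user-facing tables and summaries label rows
  1–64 so "row 32" is the central row.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `grid_resolution` | mm | 5 | chord-integration step; halving changes profiles <1% |
| spectrum `bin_width` | keV | 1 (sims use 5–10) | trade accuracy for speed; engines always share bins |
| `n_photons` | – | 10⁶ | MC budget; ~10% per-channel SE row-summed |
| `n_splits` | – | 32 | exit-direction splitting per interaction |
| `penumbra_margin` | channels | 2 | interpolation guard around shadows |
| `primary_floor` | fraction | 10⁻³ | SPR validity mask |
| bar layout | – | 20 × 2 mm over central 90% | open channels between shadows |
| `multiple_scatter_factor` | – | 1.0 | uniform surrogate for rescatter |

## What the simulator does and does not emulate

Emulated: two-exposure acquisitions (with/without phantom), lead-bar
shadows at 5.94× magnification with leakage 1.29 × 10⁻⁵, kVp-dependent
scatter and primary, the two-peaked scatter profile of a centred cylinder,
air-gap dependence on axial off-centring, per-element calibration and
16-bit compression, Poisson noise.

Not emulated: multiple scatter, Rayleigh scatter, bow-tie filtration,
focal-spot blur, anode heel effect (the 7° target angle is metadata only),
detector crosstalk and non-ideal energy response, characteristic anode
lines. Consequently absolute SPR values are those of a single-scatter
model — integrated SPR ≈ 16–39 per row for these phantoms — and the fall
of SPR with kVp, while strictly monotone at this geometry, is far shallower
than measured on hardware, where multiple scatter (strongly kVp-dependent)
dominates the effect. Passing tests therefore demonstrate the correctness
of the *measurement chain* and the qualitative physics, not hardware-level
scatter magnitudes.

## Problem sizes used in validation

Acceptance-level checks run the full 64 × 912 geometry: the kVp sweep and
phantom comparison with 5 keV bins and 5 mm steps; off-centring with 10 keV
bins and 10 mm steps; the MC/quadrature comparison at 10⁶ photons with
10 keV bins. Unit tests use a 8 × 228 scaled geometry for mechanical
properties; trend assertions that depend on the full fan and cone (kVp
monotonicity, air-gap monotonicity of integrated SPR) are made only at the
full geometry, where they are robust — at strongly scaled geometries the
competing channel-coverage effects can reverse them.

## Known limitations

* Single-scatter magnitudes; see above.
* The free-electron Compton fraction slightly overestimates scattering
  below ~20 keV (binding effects); filtration leaves little fluence there.
* Lead attenuation between 13–16 keV (L edges) is smoothed.
* The cone-illumination model freezes the beam z-width at the
  phantom-centre depth; row-edge scatter is approximate at the few-percent
  level.
* Off-centring is axial only (along the source–detector axis); lateral
  off-centring is out of scope.
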