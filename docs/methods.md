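# Methods

## Scope and model

`ablasim` simulates microwave ablation (MWA) of liver tissue (or a
tissue-mimicking gel phantom) by a water-cooled 2.45 GHz coaxial monopole
needle in a 2D axisymmetric (r, z) domain, with z = 0 at the needle tip and
+z toward the hub. The pipeline is: frequency-domain EM solve → dielectric
heating (SAR) → transient Pennes bioheat → Arrhenius / critical-temperature
necrosis maps → solid-of-revolution 3D zones → overlap and surface-distance
metrics against a segmented reference.

Everything is SI internally (K, m, s, W); temperatures convert to °C only at
the damage-model and reporting boundaries, because the Arrhenius integrand
is conventionally written with T(°C) + 273.15.

## Applicator and domain geometry

The needle is a monopole coax: copper inner conductor, PTFE dielectric
(ε_r = 2.03), copper outer conductor interrupted by a radiating slot
centered 25 mm above the tip, a catheter sheath (ε_r = 2.6) and a ceramic
tip. The true internals of the commercial device are proprietary; nominal
layer radii follow a 50 Ω PTFE coax inside the published 1.45 mm outer
diameter (inner conductor 0.145 mm, dielectric to 0.50 mm, outer conductor
to 0.60 mm, catheter to 0.725 mm), all configurable. The slot width is not
published either; the default is 1.0 mm (a typical monopole gap) and it is
deliberately exposed for sensitivity studies. The tip permittivity defaults
to 9 (alumina-like); it is likewise unpublished.

The phantom domain is a 102.9 mm diameter, 125 mm tall gel column with the
tip 80 mm below the surface; the clinical domain is the same cylinder of
perfused liver with an ellipsoidal tumor (half-axes 4.35 mm × 5.5 mm,
centered on the axis at the slot height). Material constants (permittivity,
conductivity, density, specific heat, thermal conductivity, perfusion,
metabolic heat, blood properties) are the standard 2.45 GHz liver/tumor
parameter set; the phantom medium uses the liver values with perfusion and
metabolism zeroed, since only those two terms are dropped for a gel.

Rasterization produces a graded tensor grid whose edges snap exactly to the
needle layer radii and the tip/slot z positions, so every layer is resolved
at any policy setting. Cells are finest (0.1 mm default, 0.05 mm available)
at the needle wall and slot and coarsen geometrically to a 1.0 mm cap.
Revolved cell volumes sum to the analytic cylinder volume to 1e-9 relative
by construction.

## EM solve

By azimuthal symmetry the fields reduce to H_φ(r, z) with

d/dz[(1/ε_c) dH/dz] + d/dr[(1/ε_c)(1/r) d(rH)/dr] + ω²μ₀H = 0,
ε_c = ε₀ε_r − iσ/ω  (e^{+iωt}),

discretized on a staggered grid (H_φ at cell centers, E_z on radial faces,
E_r on axial faces, face permittivities averaged). Copper cells are
eliminated as perfect conductors (H = 0, zero tangential E on conductor
faces). The excitation is an impressed 1/r TEM profile across the coax
dielectric at the top boundary with unit amplitude; because all cable and
matching losses are folded into a single delivered-power number, the
absolute level is set afterwards by scaling the SAR so that
∫ Q_ext dV = P_in exactly (1e-9 relative). The outer-radius and bottom
boundaries carry a 16-cell stretched-coordinate absorbing layer
(cubic-graded complex stretch, amplitude 6, applied as an overlay on the
physical cells including the complex radial metric); the top boundary is a
conducting cap carrying the port. The axis uses the regularity condition
E_z(0) = 2H₀/(iωε r_c0).

A 1D lossy-slab restriction of the same kernel verifies the discretization
against the closed-form plane-wave attenuation constant
α = ω√(µε/2·(√(1+(σ/ωε)²)−1)); for liver at 2.45 GHz both give ≈48 Np/m
(0.06% apart at the default 0.2 mm cell).

Known limitation: the impressed (hard) port does not model antenna
mismatch. A real port deposits P_in·(1−|S11|²) in tissue; the normalization
contract used here deposits all of P_in. This is the right contract when
the delivered power is a measured input, but it makes absolute temperatures
upper-bound estimates for a poorly matched antenna (see below).

## Bioheat solve

Conservative finite volumes with harmonic-mean face conductivities and
implicit backward Euler (default Δt = 0.5 s, LU-factored once). The
applicator interior is excluded from the solve; circulating coolant is a
Robin flux h·(T_cool − T) on every needle-wall face, with defaults
h = 500 W/(m² K) and coolant 7 °C (phantom) / 20 °C (clinical). Outer
boundaries are held at the initial temperature (they are ≥25 mm from the
heated zone over 10 min); an insulated variant exists as an oracle hook.
Perfusion ρ_b C_b ω_b (T_b − T) and metabolic heat Q_m enter only in the
clinical case. Vaporization latent heat above 100 °C, temperature-dependent
properties, and discrete-vessel heat sinks are deliberately not modelled.

Checks: insulated no-source runs are constant to machine precision; with
conduction suppressed (k = 0 hook) the perfusion-only relaxation matches
T_b + ΔT·e^{−t/τ} with τ = ρC_p/(ρ_b C_b ω_b) = 292.95 s for the liver
constants (backward Euler bias ≈0.09% at Δt = 0.5 s); the per-step energy
balance closes to 0.1%; the scheme is an M-matrix, so the discrete maximum
principle holds.

Snapshots are kept at 1 s cadence (configurable), which also sets the
accuracy of the damage integral near steep ramps. Probes are sampled
bilinearly; at a grid node the nodal value is exact.

## Damage models

The Arrhenius integral Ω = ∫A·exp(−E_a/(R(T+273.15)))dt uses the standard
liver pair A = 7.39e39 1/s (the printed "L/s" is read as 1/s on dimensional
grounds) and E_a = 2.577e5 J/mol, accumulated trapezoidally over the
snapshot cadence. Necrosis is Ω strictly > 1 (63% completion); the
critical-temperature mask is T ≥ 60 °C, by default on the running maximum
field (necrosis is irreversible), with a final-time mode for end-time
isolines. Both thresholds are exposed; a 98% completed-fraction display
threshold (fraction > 0.98 ⇔ Ω > 3.91) can be obtained by setting
`omega_threshold` accordingly.

## Zones and metrics

Masks become sub-cell contours via marching squares on the padded indicator
(padding forces closed loops; axis crossings are clamped to r ≥ 0). The
contour is revolved: voxels (default 0.5 mm isotropic) whose center radius
falls inside the polygon belong to the solid; the lattice is offset half a
voxel so centers never sit exactly on axis-aligned boundaries (which would
bias volumes systematically). Cylinder and sphere test solids land within
2% (measured ≈0.1–1%) of the analytic volumes at 0.5 mm.

Registration uses a supplied rigid matrix when given — mirroring a manually
derived registration that must not be silently refined — and otherwise
point-to-point ICP on surface-voxel centers from a centroid-aligned start.
Metrics: Dice 2|A∩B|/(|A|+|B|) after nearest-neighbour resampling of the
moving mask onto the fixed grid; Hausdorff as the symmetric max of directed
maximum surface distances; "Euclidean distance" as the mean symmetric
nearest-surface distance (the common companion metric; reported as such,
since the term is ambiguous in the literature). Surfaces are voxel centers
with at least one 6-neighbour outside. All three equal brute-force
all-pairs computation on small masks.

## Synthetic fixtures

`generate_reference_zone` emulates a radiologist's segmentation: a voxelized
ellipsoid, optionally minus a cylinder (the heat-sink imprint of a vessel
crossing the zone), with smooth seeded boundary jitter standing in for
manual-segmentation roughness. `generate_sensor_series` emulates fiber-optic
probe recordings as a saturating exponential with seeded Gaussian noise.
These reproduce the *structure* of real validation data, not its physics:
passing metrics against them demonstrates the comparison machinery, not
clinical accuracy. Each generator is bit-deterministic for a fixed seed.

## Baseline results and their sensitivity

The phantom baseline (35 W delivered, 600 s, default grid of ~13.6k cells;
EM solve <1 s, thermal march ~3 s) yields an Arrhenius zone strictly larger
than the 60 °C isoline zone (revolved volumes ≈31.7 vs ≈21.6 cm³, ratio ≈1.47) — the expected ordering, since first-order kinetics accumulate
damage below 60 °C over 10 min.

The peak tissue temperature is ≈208 °C, above the ~122 °C reported for
finite-element simulations of this device. The value is grid-converged
(207.8 → 207.2 °C at 2.3× cells) and insensitive to insertion depth
(±1%), and the global energy balance closes; the gap is attributable to
modelling choices, not numerics: (a) the all-power-deposited normalization
(no mismatch loss), (b) the nominal needle internals, which concentrate
deposition at the slot more than a reconstruction that smears the heating
along the shaft, and (c) the coolant film coefficient, which is unpublished
and decisive near the needle — raising h from 500 to 5000 W/(m² K) (upper
range for forced water cooling in a narrow annulus) lowers the peak to
≈137 °C. Probe temperatures a centimeter away (≈86 °C at r = 10 mm) are far
less sensitive to all three. Treat absolute near-field temperatures as
upper bounds until the applicator internals are calibrated; the defaults
are kept as stated rather than adjusted to match any published value.

## Numerical knobs worth knowing

- `GridPolicy(fine_cell, max_cell, cells_per_layer, mid_cell)` — defaults
  0.1 mm / 1.0 mm; `GridPolicy.coarse()` for quick runs (0.25/1.5 mm).
- `ThermalConfig.time_step` (0.5 s) — backward Euler is unconditionally
  stable; halving Δt moves 600 s probe values by <0.5%.
- `ThermalConfig.snapshot_interval` (1 s) — damage-integral cadence.
- `EMConfig.absorbing_boundary_thickness` (16 cells) and
  `absorbing_strength` (6).
- `DamageParams.omega_threshold` (1.0, strict >) and `critical_mode`
  (`max_over_time` default; ties at the 60 °C threshold use ≥).
- `voxel_spacing` (0.5 mm) for revolved volumes; nearest-neighbour
  resampling preserves binary masks.

Degenerate inputs are handled explicitly: zero-duration runs return the
initial snapshot with empty masks and no metrics; empty contours revolve to
empty volumes; metrics on two empty volumes raise.
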