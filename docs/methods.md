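# Methods

This note documents the models behind `seacanopy`, the defaults and why
they were chosen, the numerical choices, and what the synthetic fixtures
do and do not capture.

## Canopy morphology

Plants are generated parametrically: a vertical stem of `n_internodes`
segments, branches attached to nodes on the upper 40% of the stem
(branch elevation 15–45 degrees from vertical), and terminal clusters of
2–4 strap leaves at branch tips and the stem apex.  Leaves are
zero-thickness, two-sided rectangular strips triangulated along a
three-segment midrib; stems and branches are thin ribbons (default stem
diameter 2 mm, branches one-third slimmer) that occlude light but carry no
leaf area.  All dimensions are drawn from per-archetype uniform ranges
(stem height 0.32–0.58 m, leaf length 4.5–11 cm, width 6–10 mm), seeded
for bitwise reproducibility.

The fixture pool's **leaf inclination range of 67–86 degrees from
horizontal**, together with the tufted branching and the leaf optical
constants below, is the package's one calibrated morphological setting:
it was tuned once so that upright canopies reproduce the observed bulk
extinction of these meadows — midday substrate transmittance following
roughly 100·exp(-0.29·LAI) — and then frozen.  Erect, clumped leaf tufts
are also what this growth form actually looks like; a random
(spherical) leaf-angle distribution would give a markedly steeper decay
(b ≈ 0.5).

**LAI convention**: one-sided projected leaf area per substrate area.
Stems are excluded from LAI but retained as optical occluders; this is the
near-universal convention, though it means stem-rich canopies extinguish
slightly more light per unit LAI.

Canopy assembly draws plants from the pool until the target leaf area is
bracketed, prunes trailing leaves off the last plant, and absorbs the
residual (< 5%) with a uniform leaf-width scaling, landing within ±2% of
the target LAI.  Placement is seeded uniform with a minimum periodic stem
spacing.  The 0.2 m × 0.2 m tile is periodic in x and y: the optical
solver wraps every ray, so the modelled meadow is horizontally uniform and
edge-free.

## Plant dynamics

Skeletons are point-mass graphs (masses 1 g per node; plants treated as
neutrally buoyant, so the upright rest pose is an exact equilibrium).
The integrator is semi-implicit Euler (dt = 2 ms) followed by eight
Gauss-Seidel sweeps of distance-constraint projection over the structural
edges plus grandparent–child bending constraints at half stiffness —
the standard cloth-simulation recipe.  Forcing is a horizontal body force
A·sin(2πt/T) on every node with linear drag; defaults A = 12 mN,
T = 3 s, drag 0.08 N·s/m were chosen to produce a vigorous but
inextensible (edge strain < 1%) forward-and-backward sway with tip
excursions of ~0.15 m, and are not calibrated to any specific sea state.
Two periods of spin-up are discarded; snapshots are taken at evenly
spaced phases of the final period and re-skinned by rotating each mesh
vertex rigidly with its skeleton edge (leaf area is preserved exactly
per segment).

## Light field

Spectral grid: 17 contiguous 20 nm bands over 400–740 nm; PAR integrates
the 15 bands below 700 nm with photon conversion E·λ/(h c N_A).
Directions: 18 equal-angle zenith bins over the downward hemisphere.
Each ring's quadrature direction sits at its irradiance-weighted mean
zenith and carries the exact ring factor π(cos²θ₀ − cos²θ₁), so a uniform
radiance integrates to exactly πL on a horizontal surface.

The clear-sky model is deliberately simple: a 5778 K Planck shape scaled
to 530 W m⁻² (400–740 nm, normal incidence), Rayleigh (λ⁻⁴·⁰⁸) plus
Ångström aerosol (β = 0.08, λ⁻¹·³) extinction with Kasten–Young airmass,
and half of the extinguished flux returned as isotropic diffuse skylight.
Absolute dose is therefore only approximate; all canopy results are
interpreted relative to the top-of-canopy irradiance, which is why the
shading treatments and saturation thresholds — not the absolute solar
constant — carry the analysis.

Solar geometry uses the NOAA/Spencer ephemeris.  The diurnal grid is 12
hour-centres in apparent solar time spanning daylight, with the day's
declination held fixed: mirrored hours then have *identical* zeniths, an
exact symmetry the experiment driver exploits to halve the optical work.
Night contributes zero, so a 24 h integral equals the 12-point daylight
sum and the H^A_sat ceiling of 1200 %·h is exact.

Air–water interface: Snell refraction with n = 1.34 and per-zenith-bin
unpolarised Fresnel transmission (the direct beam occupies its own bin, so
it receives exact beam Fresnel; diffuse bins average ≈ 0.93–0.94).  The
water column attenuates each bin as a beam by exp(−(a+b_b)z/cosθ) and adds
an isotropised single-scattering source (half of the scattered flux,
diffuse mean-path factor 2, numerically integrated over 24 layers),
confined to the Snell cone — all downwelling light under a flat surface
lies within 48.6°.  Full invariant-embedding radiative transfer is out of
scope.  The packaged IOPs are representative pure-water absorption plus a
CDOM exponential (a_g(440) = 0.1253 m⁻¹, slope 0.015 nm⁻¹) and a small
backscatter; the CDOM magnitude is the second frozen calibration, set so
k_d(PAR) over the 0–4.5 m column is 0.200 m⁻¹.

Shading is a spectrally and directionally neutral multiplier (1 − s),
applied to the top-of-canopy radiance; levels {0, 10, 25, 40, 50, 60, 70,
85, 95}%.

## Canopy radiative transfer

All surfaces are two-sided Lambertian reflector/transmitters with band
spectra ρ(λ), τ(λ), ρ+τ ≤ 1.  Defaults: a parametric green leaf (ρ peaking
at 0.28 and τ at 0.20 near 555 nm, strongly absorbing in blue and red,
reflective above 700 nm — the range reported for seagrass leaves), an
opaque brown stem (ρ = 0.15), and sand with mean reflectance exactly 0.33.
Leaf spectra are swappable from two-column CSV.

**Direct illumination.**  Scenes are refined so leaf facets are ≤ 0.5 cm²
(substrate and stems 8× coarser).  For every facet, sky visibility is ray
cast along each quadrature direction through the periodically wrapped
scene (2D-DDA grid traversal, Möller–Trumbore intersection, ε = 10⁻⁷ m,
self-hits excluded by facet id).  Two details matter for energy fidelity:
each facet's azimuth samples are rotated by a per-facet golden-angle
phase (shared azimuths alias against the anisotropic canopy and bias the
intercepted power by ~2%), and visibility is sampled at three points per
facet (centroid–vertex midpoints), which counts partially occluded and
interpenetrating facets fractionally.  Within-canopy water absorption
exp(−a·path) is applied along each ray.

**Multiple scattering.**  Exchange factors are estimated by seeded
cosine-weighted Monte-Carlo rays from both faces of every facet (splitmix64
streams per face, so results are independent of traversal order), giving a
sparse flux matrix with per-band water attenuation on each path.  The
Lambertian equilibrium E = E_direct + M·B(E), with face radiosity
B = ρ·E_same + τ·E_opposite, is solved by Jacobi gathering; convergence is
declared when total incident power changes by < 10⁻⁴ (relative), normally
4–6 sweeps, capped at 20.  The solution is exactly linear in the boundary
radiance (same ray set, scale-invariant stopping rule), which the test
suite asserts to 10⁻⁹.

**Energy audit.**  With water absorption forced to zero, the closure
|E_in − E_sky − E_absorbed|/E_in is 0.3–1.0% across the fixture canopies
at default resolution — residual discretisation error from finite facets
and finite quadrature.

**Exploited linearities.**  Because shading is a scalar on the boundary
radiance and the transfer operator is linear, the saturated fraction under
shading s equals thresholding the *unshaded* leaf-PAR field at E_k/(1−s);
the factorial driver therefore solves each (LAI, structure, hour) cell
once and derives all nine shading levels and all E_k values from it, and
solves only the six unique morning zeniths.  Both shortcuts are exact
(asserted to 10⁻⁹), not approximations.

## Saturation metrics

"% leaf area at or above E_k" is area-weighted and inclusive (≥); each
leaf facet's PAR is the sum of both face incidences (a thin leaf's
photosystems receive light from both sides).  H^A_sat is a rectangle-rule
sum over the 12 hourly points (1 h widths).  Surfaces over LAI × shading
assert double monotonicity and the [0, 1200] range; isoclines (default
levels 50, 100, 200 … 800) are extracted by marching squares on the
bilinear surface.  The equivalent-unshaded-LAI query inverts the
unshaded column by monotone interpolation and flags extrapolation beyond
the densest grid canopy rather than returning a silent number.

## Problem sizes and defaults

Default resolution: 0.5 cm² leaf facets, 18 zenith × 8 azimuth quadrature,
32 scatter rays per face — used for the energy audit.  Reduced resolution
(2 cm² facets, 16 scatter rays) is used for the transmittance sweep and
H^A_sat surfaces, where the metrics are area-integrated and insensitive to
facet size; spot checks at default resolution agree within the seed-to-seed
spread.  A full low-wave surface (5 LAI × 9 shadings × 12 hours, E_k 50)
is ~30 radiosity solves and runs in a few minutes on one CPU; the complete
8100-run factorial decomposes into 450 solves.

## What the synthetic fixtures do and do not show

The plant generator reproduces the architecture, size range and erect
clumped habit of the target growth form, and is calibrated to the meadow's
bulk light extinction; it does not reproduce any individual sampled plant,
epiphyte load, leaf-level optical variability, or canopy-flow interaction
(wave forcing is a kinematic stand-in, not hydrodynamics).  Passing tests
therefore demonstrate the *model machinery* — energy-conserving transfer,
correct metric reductions, the LAI/shading trade-off structure — under
realistic canopy geometry, not a field validation.  Absolute daily doses
inherit the simplified sky model's bias; relative quantities (shading
responses, isocline shapes, equivalences) are the supported outputs.

## Known limitations

- One leaf ρ/τ spectrum per run; no inter- or intra-plant variability.
- The water column has no cloud, surface-wave focusing, Raman or
  fluorescence effects; turbidity enters only as absorption along
  within-canopy paths (plus the boundary-condition attenuation).
- The single-scattering diffuse term underestimates multiple scattering
  in very turbid water; the k_d anchor compensates at the packaged IOPs.
- Monte-Carlo exchange factors make per-facet irradiances noisy at the
  few-percent level; area-integrated metrics are much tighter.
- Movement snapshots re-skin leaves rigidly per segment; leaves do not
  bend within a segment, and plant–plant collisions are ignored.
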