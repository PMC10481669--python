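# Methods

## The pressure model

The lobule is idealized as a radially symmetric cylinder: a central vein of
radius ρ₀ on the axis, portal boundary at the lobule radius L, and all
canalicular geometry averaged into radial profiles. Water crosses the apical
membrane driven by the osmotic/hydrostatic imbalance `RT(c − c₀) − p`;
osmolytes are secreted at rate `g` and advected outward; the canalicular
network acts as a porous medium with Darcy resistance
`K = 8μτ²/(ε_BC r_BC² f)`, the Hagen–Poiseuille resistance of a bundle of
tortuous cylinders of which a fraction `f` of the cross-section is open to
flow. The model is steady-state, single-osmolyte, and radially symmetric; it
resolves no individual canaliculi, no time dependence and no bile-acid
speciation.

Assumptions worth keeping in mind:

- `c₀` (300 mmol/l) and `κ` (4.7×10⁻¹⁰ m/(Pa·s)) are literature constants;
  temperature is never stated alongside them, so body temperature
  T = 310 K is the default (it only enters through RT).
- τ = 1.8 and f = 0.28 are used for both regimes (measured for disease,
  "close to" control measurements). An optional linear radial profile for
  `f` exists behind `SyntheticConfig.focusing_gradient` but defaults to off.
- `g` is inherited from prior work and not printed; the default workflow
  calibrates a constant `g` so the control regime reproduces a reference
  axis-median pressure of 1922 Pa (`calibrate_secretion`, monotone bracketed
  root find). The same `g` is then applied to the disease regime — bile
  load is deliberately not a per-patient fit.

## Numerics

Eliminating `c = G/(ρw)` leaves the states `u = ρw` and `p`. At the central
vein both `G` and `u` vanish; the limiting concentration `c*` solves
`κA RT c*² − κA(RTc₀ + p₀)c* − g = 0` (positive root; for g > 0 the osmotic
driving force is then `g/(κAc*) > 0`). Integration starts at
`ρ₀ + δ` with `δ = 10⁻³(L − ρ₀)` from `u(ρ₀+δ) = G(ρ₀+δ)/c*` — the
osmolyte-balance-consistent form of the leading-order series
`u ≈ ρ₀κA(RT(c*−c₀) − p₀)δ`; using the quadrature-grid `G` here avoids a
spurious concentration transient at the first step.

- The initial-value integrator is LSODA (the transverse relaxation toward
  the osmolyte quasi-equilibrium makes the system stiff) with the analytic
  Jacobian supplied; relative tolerance 1e-8 by default. Radau is available
  and used by the cohort runner at rtol 1e-6, where thousands of solves are
  needed and terminal pressures are only read at the Pascal level.
- Shooting: the residual `r(p₀) = p(L; p₀) − p_L` is increasing in `p₀`
  (raising the central pressure throttles influx and shrinks the Darcy
  drop), so the bracket expands geometrically upward from `p_L` and Brent's
  method refines it. Terminal tolerance 0.1 Pa by default (0.5 Pa in the
  cohort runner); a polish pass re-brackets if the slope makes the first
  root exceed the tolerance. A previous solve's `p₀` can seed the bracket
  (`p0_hint`) without affecting the answer.
- Degenerate limits are returned analytically: κ = 0 or `G ≡ 0` give
  `w ≡ 0`, `p ≡ p_L` exactly.
- `G` uses trapezoid quadrature on the geometry grid; profiles are linearly
  interpolated between grid points.
- Zone summaries: 11 equal-width radial zones (0 pericentral … 10
  periportal), per-zone median pressure, elevation = zone-0 median minus
  zone-10 median. The "axis median" is the median of the pointwise profile
  (canonical) with the median-of-zone-medians also reported, since the two
  conventions differ slightly on a discretized profile.

Conservation diagnostics (`water_balance_residual`,
`osmolyte_balance_residual`) check `L·w(L) = ∫ρκA(RT(c−c₀)−p)dρ` from the
dense solver output (Simpson on 4001 points) and `ρcw = G` pointwise; both
sit below 1e-5 relative at default tolerances. An independent collocation
solution (scaled states, `scipy.integrate.solve_bvp`) agrees with the
shooting solution to better than 1e-4 relative in `p` in the test suite.

## The synthetic lobule generator

The generator produces the statistical structure the analysis consumes, not
images and not patient-specific geometry:

- **Radial profiles** (`gen_radial_geometry`): ε_BC ≈ 3.5% with a mild
  mid-lobular peak, r_BC = 0.6 μm baseline with a mild periportal increase,
  apical density closed by the cylinder-bundle identity `A = 2ε_BC/r_BC`.
  Disease: L = 968 μm (vs 512 μm), radii ×1.116, volume fraction ×0.901,
  portal pressure 2000 Pa (vs 1000 Pa).
- **Networks** (`gen_network`): the sampled tissue is a CV→PV strip of
  constant 300 μm arc width and 100 μm depth — emulating the stitched tile
  strips such axes are imaged as — with uniform node density (200 nodes per
  zone in control; 400 in disease, whose zones are ~2× wider, keeping
  density matched). Edges are k-nearest-neighbour (k = 4) connections,
  stitched into one component, thinned by a background dropout (5%); edge
  radii are flat along the axis (noise only), deliberately trend-free so the
  per-zone network volume is statistically flat. A Bernoulli
  `rosette_fraction` of edges (0.2% control, 2% disease) is re-assigned
  radii uniform in [3, 8] μm, and each rosette disconnects its neighbouring
  baseline edges with probability `rosette_disconnection = 0.65` — the
  mechanical expression of rosettes consuming and disconnecting canaliculi.
- **Sections** (`gen_section_table`): rosette rows (diameter > 6 μm, > 2
  bounding cells) with Sox9+/pan-CK+ cells at configured probabilities
  (28% / 4%), plus normal lumina and wide duct-like lumina bounded by only
  two cells that the counting rule must reject.
- **Cohorts** (`run_cohort`): per-patient severity jitter scales the rosette
  fraction and the excess dilation together (rosette load co-varies with
  dilation); per-patient duct pressure is jittered (sd 150 Pa) reflecting
  the wide physiological spread of biliary boundary pressures. The conducting
  geometry derived from a network (`network_to_geometry`) clamps
  rosette-band segments to the median baseline calibre: the porous-medium
  law describes narrow canaliculi, and a handful of giant segments would
  otherwise dominate the volume-weighted effective radius; dropping them
  entirely would instead leave conductance gaps tracking the chance rosette
  count.

Null cohorts (for validating the correlation stage) remove every engineered
effect: both groups use the control template at the control boundary
pressure, one common rosette fraction (set at the disease level so the
ratio is informative rather than zero-inflated), and the rosette
disconnection mechanism off. Bootstrap intervals for pooled correlations
resample whole patients, because per-zone observations within an axis share
that axis's geometry and boundary pressure.

### What passing tests do and do not show

The generator reproduces the *directions* and rough magnitudes of the
disease phenotype: larger lobules, dilated canaliculi, rosettes throughout
the axis, reduced connectivity, higher predicted pressures, a positive
pooled correlation of rosette load with pressure and a negative one with
connectivity. It does not reproduce image-derived texture: no spatial
clustering of rosettes (a knob exists but is off), no fibrosis, no
patient-specific geometry, and the disease networks *gain* volume from
rosette insertion whereas real PSC reconstructions lose ~10% network volume
(the profile generator applies that factor, the network generator does
not). One knob cannot match everything: `rosette_disconnection = 0.65`
reproduces the pooled rosette–connectivity correlation at roughly the
reported magnitude while overshooting the zone-profile connectivity deficit
(≈ −40% vs ≈ −17% reported); 0.5 would match the profile deficit but leave
the pooled correlation fragile. The correlation structure is what this
pipeline exercises, so the default favours it. Tests passing on these
synthetics validate the *code* — formulas, conservation laws, counting
rules, statistics — not the biology of any particular patient.

## Statistics

Pearson correlations pool one observation per (patient, axis, zone) with no
within-sample averaging first. Zone profiles are compared between regimes
with a paired two-tailed t-test across zones (axes averaged per patient
first); axis-median pressures with an unpaired two-tailed t-test; p-values
are reported, never used for gating, and no multiple-testing correction is
applied. Percent changes are `100·(disease − control)/control` on
regime-mean statistics.

## Problem sizes

Defaults were chosen so a full cohort replicate (3 control axes + 12 disease
axes: generation, morphometry, geometry, calibration and 15 boundary-value
solves) completes in seconds: 2200–4400 nodes per network, 22 radial shells
for derived geometry, 201-point analytic profiles, shooting at 0.1–0.5 Pa
terminal tolerance. The statistical-structure checks run 50 cohort
replicates plus a null cohort with 1000 bootstrap resamples.

## Known limitations

- The radial symmetry of the model collapses all azimuthal structure; there
  is no network-resolved 3D flow solve.
- The connectivity statistic (1/number of components in a zone-induced
  subgraph) depends on how much tissue a zone samples; it is comparable
  across this generator's regimes only because the strip geometry keeps
  node density uniform.
- The crossing-density normalization (zone boundary area = strip width ×
  depth, or arc length × depth on the full annulus) is one defensible
  choice among several; it is configurable.
- Calibration targets a single reference median; it does not constrain the
  shape of `g(ρ)`, only its constant magnitude.
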