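# biliflow

Bile drains from the liver lobule against the direction of blood flow: water
enters the sub-micron bile canaliculi osmotically across the hepatocyte
apical membrane and percolates outward from the central vein (CV) to the
portal vein (PV) through a dense tubular network. Canalicular pressure cannot
be measured directly, so it has to be predicted from the network geometry. In
cholestatic disease (e.g. primary sclerosing cholangitis, PSC) the network
remodels: canaliculi dilate, multicellular "liver cell rosettes" (lumina
wider than 6 μm bounded by more than two hepatocytes) appear, and network
connectivity drops — changes that raise the predicted biliary pressure.

`biliflow` is a small scientific Python package for people studying this
system. It provides:

- **a lobule-scale bile-pressure model** — osmotic water influx plus Darcy
  flow on a radially symmetric lobule annulus, solved as a singular
  boundary-value problem by shooting;
- **zone-resolved morphometry** of 3D canalicular network graphs along the
  CV–PV axis (radius, volume fraction, surface/volume, connectivity,
  boundary crossings, junction density, lobule radii);
- **rosette quantification** in 3D (detection, radius histogram, volume
  estimate, rosette/network volume ratio) and on 2D sections (counting and
  Sox9 / pan-CK marker classification);
- **cohort statistics** (Pearson correlations, paired/unpaired t-tests,
  percent changes) and a **synthetic-data generator** that emulates control
  and PSC lobules so the entire pipeline runs and is testable without any
  imaging data.

## Model

On the annulus ρ₀ ≤ ρ ≤ L (central-vein radius ρ₀, lobule radius L), mass
conservation for water and osmolytes plus Darcy's law give, for radial bulk
velocity `w`, canalicular pressure `p` and osmolyte concentration `c`:

    (ρw)′/ρ = κ A (RT (c − c₀) − p)
    (ρcw)′/ρ = g
    p′ = −K(ρ) w

with boundary conditions `w(ρ₀) = 0` and `p(L) = p_L`, where `A` is the
apical surface density, `κ` the membrane water permeability, `c₀` the
hepatocyte osmolyte concentration, `g` the osmolyte secretion rate and the
flow resistance follows from porous-media theory:

    K(ρ) = 8 μ τ² / (ε_BC(ρ) · r_BC(ρ)² · f(ρ))

(`μ` bile viscosity, `τ` tortuosity, `ε_BC` canalicular volume fraction,
`r_BC` effective canalicular radius, `f` free lumen ratio). The osmolyte
equation integrates to `ρcw = G(ρ) = ∫ ρ̃ g dρ̃`; eliminating `c` leaves a
two-state system in `u = ρw` and `p` that is singular at the central vein
(`c = G/u → 0/0`). The solver starts a small offset off the axis from the
analytic limit of `c` (the positive root of a quadratic fixed point) and
finds the central pressure `p₀` by bracketed shooting on `p(L) − p_L`.
Canaliculus velocity follows as `w_c = w/ε_BC`. Defaults:
`μ = 9.2×10⁻⁴ Pa·s`, `κ = 4.7×10⁻¹⁰ m/(Pa·s)`, `c₀ = 300 mmol/l`, `τ = 1.8`,
`f = 0.28`, `p_L = 1000 Pa` (control) / `2000 Pa` (disease).

## Worked example

```python
import biliflow as bf

cfg = bf.SyntheticConfig.for_regime("control", seed=7)
geom = bf.gen_radial_geometry(cfg)
params = bf.BileParams(
    kappa=4.7e-10, R=8.314462618, T=310.0, c0=300.0, mu=9.2e-4,
    p_duct=1000.0, g=1.0,
)
sol = bf.solve_pressure(geom, params)
summary = bf.zone_pressure_summary(sol)
print(f"central pressure p0      : {sol.p0:8.1f} Pa")
print(f"axis-median pressure     : {summary.axis_median:8.1f} Pa")
print(f"pericentral elevation    : {summary.elevation:8.1f} Pa")
print(f"terminal residual        : {sol.residual:8.2g} Pa")

net = bf.gen_network(cfg)
stats = bf.zone_statistics(net)
segments, counts = bf.detect_rosettes(net)
v_zone, v_total = bf.rosette_volume(counts)
print(f"rosette segments         : {counts.total}")
print(f"estimated rosette volume : {v_total:8.1f} um^3")
print(f"zone-0 connectivity      : {stats.loc[0, 'connectivity']:.3f}")
```

prints

```
central pressure p0      :   2002.4 Pa
axis-median pressure     :   1711.7 Pa
pericentral elevation    :    911.4 Pa
terminal residual        :   0.0014 Pa
rosette segments         : 11
estimated rosette volume :  10578.4 um^3
zone-0 connectivity      : 1.000
```

Read: with a constant secretion rate of 1 mmol/(l·s) the control lobule
carries a pressure of ~2000 Pa at the central vein that decays to the
1000 Pa duct boundary — bile is driven outward, opposite to blood flow, with
a pericentral-over-periportal elevation of ~900 Pa. The seeded control
network contains 11 rosette segments (diameter > 6 μm) whose estimated
volume is ~10⁴ μm³; the pericentral zone's canaliculi form a single
connected component.

`bf.run_cohort(seed=...)` chains everything: it generates a cohort of
control and PSC patient axes, quantifies each network, converts it to radial
profiles, solves the pressure problem per axis, and pools one observation
per (patient, axis, zone) to correlate the rosette/network volume ratio with
predicted pressure (positive) and with connectivity (negative).

A thin CLI mirrors the library: `biliflow generate`, `biliflow pressure`,
`biliflow netstats`, `biliflow rosettes`, `biliflow rosettes2d`,
`biliflow run` (see `biliflow --help`).

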