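# Methods

This note describes the model, its parameterization and its limitations in
the package's own terms.  Nothing here states an empirical result that the
test suite or the acceptance script does not itself compute.

## The stop-signal response

Roots slow and finally stop elongating as soil mechanical impedance rises.
The relative elongation rate is `y = 1 − (x/5000)^a` with impedance `x` in
kPa, clamped to `[0, 1]`; every phenotype ceases elongation at 5 MPa.  The
exponent `a` is the penetration ability: `a = 1` is linear, `a < 1` is a
sensitive ("plastic") stop signal, `a > 1` an insensitive one.  Axial
classes share one exponent, laterals another; the default level set
(0.2, 0.4, 0.6, 0.8, 1, 1.5, 2) yields 49 phenotypes.

## Soil profiles and pedotransfer

Two alluvial Inceptisols are built in: a sandy loam (A horizon to 73 cm,
clay loam below, sandy loam again from 115–130 cm; the 97–115 cm interval
is underdetermined, so the clay loam is extended to 115 cm) and a silt loam (silt loam to 22 cm, silty clay to 89 cm, silty
clay loam to 160 cm).  Texture classes are mapped to USDA
texture-triangle centroids; per-layer bulk densities (1.40–1.55 g cm⁻³
native) were chosen so that porosity `θs = 1 − Db/2.65` spans ≈ 0.39–0.51
across horizons and managements, a plausible porosity range for
these alluvial horizons under native and cultivated management.
Cultivation halves the A-horizon thickness and organic matter and raises
its bulk density by 10 %; deeper layers shift up unchanged.

Field capacity (−33 kPa) and wilting point (−1500 kPa) come from the
Saxton–Rawls (2006) regressions with the published density adjustment;
van Genuchten `(α, n)` are solved so the retention curve passes through
both anchors exactly (bracketed root solve on `n`, α eliminated);
`θr = 0.35·θpwp` clamped to [0.0249, 0.0911]; conductivity uses the
Mualem closure with tortuosity exponent 0.5 and the Saxton–Rawls
saturated conductivity.

Penetration resistance uses a Whalley-type log-linear pedotransfer

```
log10(PR_kPa) = 0.35·log10(|ψ_kPa| · S) + 0.93·Db + 1.26
```

with degree of saturation `S = θ/θs`, plus an optional overburden gradient
(default 0).  PR falls to ~1 MPa at field capacity and reaches ~2.5–3 MPa
at wilting point for the A horizons; surface layers dried below wilting by
evaporation reach 5 MPa and beyond.  The exact function behind the original
impedance module is not published; the coefficients are configurable.

## Water and solute dynamics

Water moves by the 1-D Richards equation on a node-centered
finite-volume grid (2 cm nodes), solved implicitly with modified-Picard
iteration (tolerance 10⁻⁶ on θ, damping after iteration 8, and a fallback
acceptance at 2·10⁻⁵ for the limit cycles that appear at perched saturated
fronts; the mass-conservative update keeps the discrete balance exact in
all cases).  The surface carries a prescribed flux; the bottom is free
drainage.  Daily macro-steps use adaptive sub-steps (initial 0.05 d,
halving on failure, floor 10⁻⁴ d), and every sub-step is audited against a
10⁻⁴ cm balance tolerance.

Evaporation is extracted from a 12 cm surface layer with exponentially
decaying weights, each node ramping from full supply at field capacity to
zero at an air-dry limit midway between θr and θpwp.  This lets the upper
topsoil — not just the surface node — dry below wilting point, which is
what hardens it.

Transpiration demand is partitioned over nodes by root length × available
water (a 0–1 ramp between wilting point and field capacity).  Each node is
additionally capped by extractable water and by a per-root-length rate
limit `0.4 cm³ cm⁻¹ d⁻¹ × availability²`.  The quadratic availability
factor represents the collapse of rhizosphere hydraulic conductivity in
drying soil; without it, dense root mats in dry topsoil would meet the
whole demand and the water-deficit scenario would produce no stress.

Nitrate moves by explicit, upwinded convection–dispersion on the day's
Darcy fluxes (CFL-limited sub-steps; `D₀ = 1.5 cm² d⁻¹`, dispersivity 2 cm,
Millington–Quirk tortuosity); bottom outflow accumulates as leached N.
Mineral N is released from an organic pool at a declining specific rate
`k(t) = 0.01·(t+1)^(−0.5) d⁻¹`.  The pool is 6 µmol cm⁻³ per % organic
matter — deliberately a small mineralizable fraction of total organic N,
so that the eroded, OM-depleted cultivated profile is genuinely
nitrogen-limited while the native profile is not.

## Root architecture

The maize parameter card: one primary axis (day 0), three seminals (day 1),
nodal whorls on days 8/12/16/20 with 4/6/8/10 roots; axial potential
elongation 2.5 cm d⁻¹ (diameter 0.1 cm), laterals 0.8 cm d⁻¹ (0.03 cm) at
2 laterals cm⁻¹ behind tissue older than 3 days; tissue density
0.12 g cm⁻³ at 40 % carbon (lateral specific root length ≈ 12 000 cm g⁻¹).
Geometry is fully 3-D (insertion angles, gravitropism, seeded azimuthal
jitter — the seed only rotates the system) but the soil is laterally
homogeneous, so only tip depth couples to soil state.  Growth is cut into
~1 cm segments; segment lengths are apportioned to soil nodes by z-overlap
for the length and surface-area depth profiles.

Per day, each tip advances by `potential × y(PR at tip) × dt`.  If the
root carbon budget cannot cover demand, axial classes are satisfied first
and the shortfall scales all lateral growth proportionally.

## Plant carbon economy

The carbon source is a light-use-efficiency model: 3 g C MJ⁻¹ ×
4·10⁻⁴ MJ cm⁻² d⁻¹ incident light × 400 cm² ground area × Beer–Lambert
interception (k = 0.6), multiplied by a saturating CO₂ factor normalized
to 1 at 270 ppm (half-saturation 200 ppm) and by a stress factor
`1 − 0.7·max(stress)` — severely stressed leaves retain 30 % of capacity;
a fully multiplicative factor makes the stress→supply→root-growth loop
bistable, flipping between zero stress and collapse on small input
changes.  Seed reserves (0.25 g C) are released over the first 10 days.

Allocation is a strict waterfall: root then shoot maintenance (0.025 and
0.01 g C g C⁻¹ d⁻¹), then shoot growth, then axial, then lateral root
growth; the residual carries to a reserve.  Shoot demand is the potential
relative growth rate (0.25 d⁻¹) capped at 65 % of post-maintenance supply:
with strict shoot priority and an uncapped exponential demand the shoot
absorbs the entire source and the root system starves, which no real
seedling does.  This cap is the package's functional-balance stand-in for
sink limitation.

Nitrate uptake is Michaelis–Menten per unit root surface
(Imax 2.5 µmol cm⁻² d⁻¹, Km 1 µmol cm⁻³, low-affinity range), capped by
available mass per node.  Stress indices follow `1 − (u − m)/(o − m)` on
cumulative quantities: for water, `o` is cumulative potential
transpiration (0.30 cm³ per cm² leaf per day) and `m = 0.3·o`; for N,
`o` is 4 % and `m` 1 % of shoot dry weight as N.  Because the index is
cumulative, it carries a germination transient while roots are a few cm
long; tests evaluate it after establishment (day 10).  A 3-day moving
average of the indices feeds back into the source.

## Scenarios

Well-watered cells receive 0.6 cm d⁻¹ at the surface throughout
(irrigation for cultivated, rain for native) — above peak
evapotranspiration but below the silty clay's saturated conductivity, so
irrigation leaches nitrate without perching water permanently.
Water-stressed cells receive 0.5 cm d⁻¹ only through day 4 and start with
the top 30 cm at 25 % of plant-available water; drought was imposed through
both the rain cutoff and the initial water state.  Native cells start with
4 µmol cm⁻³ nitrate in solution throughout the profile (mineral N
accumulated before the run) plus full mineralization; cultivated low-N
cells keep 25 % of that with the halved-OM pool; high-N adds a fertilizer
pulse restoring native-level nitrate in the top 20 cm at day 0.  The
daily coupling order is fixed: PR update → supply and allocation → root
growth and branching → water uptake and Richards → nitrate mineralization,
transport, uptake → plant state and stress update.  Runs are deterministic
given the cell-derived seed (CRC-32 of the cell identity; replicates
differ by seed).  A 40-day run on the default grids takes well under ten
seconds on one CPU.

These scenario magnitudes (cutoff day, initial water, N pools, irrigation
rate) are not printed anywhere; they were calibrated once against
qualitative signatures of the target system — water stress developing
mid-run under the water-stress regime and absent when well-watered; the
dry topsoil far harder than the wet subsoil at day 40; native plants
nitrogen-unstressed while cultivated low-N plants carry persistent
nitrogen stress — and then frozen.

## What the synthetic scenarios do and do not capture

The generator emulates vertical gradients only: layered texture, a drying
and hardening topsoil, irrigation-driven leaching, and low vs high mineral
N.  It does not represent lateral soil heterogeneity, macropores or
biopores (a major real-world path through hard soil), soil temperature,
rainfall variability within the season, root anatomy (cortical
aerenchyma, multiseriate cortical sclerenchyma), root hairs, senescence,
or second-order laterals.  Passing tests therefore show that the coupled
mechanisms reproduce the *directional* behaviour of the target system —
they do not validate absolute magnitudes against field data.

## Numerical and design notes

* Mass balances are audited at three levels: per Richards sub-step
  (10⁻⁴ cm), per nitrate step (machine precision by construction), and
  per run (water and N to 0.5 % of throughput, carbon to 10⁻⁶ relative);
  a breach aborts the run.
* D95 is the smallest depth above which 95 % of root length lies, with
  linear interpolation inside the containing 2 cm cell.  Water-availability
  classes for the root-distribution metric use 0.25/0.75 of the
  plant-available range; the water-per-carbon metric uses the final 20
  days of the 40-day run.  Landscape argmax ties break toward the smaller
  (more plastic) exponent pair.
* Known limitation: with the strict axial-before-lateral waterfall, lateral
  demand can never slow axial deepening, so the two extreme lateral
  phenotypes share an identical axial skeleton.  Their D95 difference
  comes only from the lateral length distribution, which the
  growth-reduction law bounds to a modest contrast (the fold change
  between extreme lateral phenotypes under water stress evaluates to
  ≈ 1.05–1.1, direction as expected).  A larger contrast would require
  lateral–axial competition for carbon or a heavier lateral
  parameterization.
* The cultivated silt loam perches water when surface input approaches the
  silty clay's saturated conductivity; the Picard iteration then
  limit-cycles at the saturated front with a θ amplitude of ~10⁻⁵, which
  the solver accepts under a documented fallback tolerance rather than
  grinding the sub-step to the floor.
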