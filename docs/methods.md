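# Methods

This note records the models implemented in `thermotrap`, the numerical
and design choices behind them, and what the synthetic-data round trips
do and do not demonstrate.

## Single-chamber transport model

A heat-flow chamber is a thin vertical water-filled gap (thickness
`α ≈ 170 µm`, height 50 mm for the measurement chamber, 200 mm × 60 mm
for network chambers) between a hot and a cold wall.  The package reduces
the chamber to a 2-D slab (height × gap); the width enters only through
the conversion of volumetric flow rates to per-width fluxes.  Lateral
uniformity across the 60 mm width is assumed.

**Flow.**  Instead of solving the Navier–Stokes equations numerically,
the solvent velocity is analytic — this is the package's single largest
deliberate simplification relative to a finite-element treatment, and it
is justified by the aspect ratio (300–1200 : 1), which puts the flow deep
in the lubrication/Boussinesq regime:

* the closed convection roll `v(ξ) = (ρ g β ΔT / 6 η α) · ξ (α²/4 − ξ²)`
  (ξ the distance from the gap centre; upward on the hot side), tapered
  to zero at the chamber ends over one grid cell through the
  streamfunction;
* a Poiseuille profile carrying the bottom-outflow share of the
  throughflow downward.

Water properties (ρ, β from the Kell 1975 atmospheric-pressure fit, η
from the Vogel-type correlation, documented validity 5–95 °C) are
evaluated at the film (mean) temperature.  The sensitivity of the
dimensionless group `q` to the property correlation is a few per cent.

**Solute transport.**  The drift–diffusion equation
`∂c/∂t = ∇·[D∇c − (u − S_T D ∇T) c]` is discretised finite-volume on a
uniform rectangular grid.  Face velocities are differenced from the
streamfunction at cell corners, so the discrete field is divergence-free
to machine precision.  Flux scheme: Scharfetter–Gummel (exponential)
across the gap — exact for the cross-gap drift–diffusion balance — and
*central* along the height.  The central choice is essential, not
cosmetic: an exponential/upwind vertical flux adds numerical diffusion
`D·(Pe/2·coth(Pe/2) − 1)` at the cell Péclet numbers ~1–10 typical here,
which competes directly with the Taylor-dispersion term (the `q²/10080`
denominator of the closed-form profile) and was measured to bias the
steady log-slope by 12–33 % at q ≈ 60.  With central vertical fluxes the
steady solver agrees with the closed form to < 0.2 % up to q ≈ 143 at
32 × 160 cells.  The vertical profiles are smooth on the accumulation
length, so no oscillations arise despite cell Péclet numbers above 2.

**Boundary model.**  Inflow/outflow channels are not resolved: the
inflow and the top outflow are distributed over the whole top edge with
Poiseuille weights, the bottom outflow over the bottom edge.  The
cross-gap mixing time (`α²/D ≈ 20 s`) is negligible against transit
times (hours–weeks), so the lateral position of a channel cannot affect
the outcome; the distributed form is exactly conservative cell by cell.
Walls are impermeable (zero combined drift+diffusion flux).

**Solution strategy.**  Steady states are direct sparse solves (for a
closed chamber the singular balance system is closed with the unit-mean
constraint, which the conservation structure makes exact); transients
use implicit Euler with a geometrically growing step (initial step
`α²/4D`, growth 1.25, cap duration/50).  Degenerate inputs: ΔT = 0 with
no throughflow yields exactly the uniform state; aspect ratios below 50
are refused (the thin-gap model would be invalid).

**Closed-form oracle.**  The steady profile
`c(y) = exp(−(q/120)/(1+q²/10080) · S_T ΔT y/α)`, with
`q = ΔT β g ρ α³ / 6 η D`, is the classical thermogravitational-column
series solution; the package treats it as exact by definition, reports
profiles normalized to chamber-mean 1 (matching the measurement
normalization), and validates the numerical solver against its log-slope
for q ≤ ~100.  The exponent at fixed `S_T ΔT h/α` is maximal at
`q = √10080 ≈ 100.4`.

**Steady state vs 18 h.**  At the measurement-chamber defaults the
steady bottom/top point ratio (~400-fold) is approached only on a ~150 h
timescale; after 18 h the fraction-resolved contrast is ~5-fold.
Experiments of 18 h are therefore *not* at steady state, and the
Soret-fitting pipeline deliberately matches the 18 h transient forward
model, not the steady profile.  What *is* true at 18 h is that the
fitted `S_T` is nearly independent of the assumed diffusion coefficient
(±50 % in D moves the fit by < 10 %), which is what makes literature D
values acceptable inputs.

## Soret-coefficient inference

Fraction tables (species × 4 equal-height fractions × replicates, with
fraction 1 the top) are normalized per species and replicate to mean 1,
making the analysis independent of calibration factors and absolute
concentrations.  Pairwise enrichment of A over B is the replicate mean
of the per-replicate concentration ratio minus 1 — ratios are formed
*before* averaging because the temperature difference varies by 1–2 K
between replicates and shifts all species of a replicate together;
averaging first would distort the enrichment.  The pool-enrichment
statistic compares one species with the mean of all species; the ratio
form is the default (a printed variant that mixes a ratio label with a
difference formula is available behind `literal_difference=True` for
literal reproduction).

Fitting: per replicate, a bounded least squares in `S_T ∈ [−0.01, 0.02]`
matches the transient (18 h) forward model's four fraction means to the
measured ones, seeded by a coarse log-spaced scan over both signs (the
multi-start stage; the objective is unimodal in `S_T`, so scan + local
refinement is robust).  Estimates at the search boundary are flagged.
Default diffusion coefficients: 8e-10 m²/s for amino acids, 1.4e-9 m²/s
for 2-aminoazoles and nucleotide components; configurable per species.

**Replicate error decomposition.**  For every unordered pair of
replicates, the fitted `S_T` values of all species of a mixture are
regressed through the origin; a common temperature offset appears as a
slope ≠ 1.  The systematic error is the mean of `max(slope, 1/slope) − 1`
(the symmetric form is direction-independent and returns exactly 0.10
for a pure 10 % offset); the random error is the pooled residual s.d.
divided by √2 (both replicates carry noise), which recovers an injected
Gaussian σ without bias.

## Transfer tables and the crack network

Network chambers are never solved during network runs; their steady
responses are precomputed on a grid over (ΔT, D, S_T, Q_in,
bottom-outflow share) and interpolated multilinearly (flow-rate axis in
log space).  The default axes reproduce the reference sweep
(ΔT 0–12 K; D {800, 1400} µm²/s; S_T {1, 4, 8, 12}·10⁻³ 1/K;
Q_in {0.01…10} nl/s; share {1…100} %), 4368 cells.  (A printed total of
7,332 profiles does not factor over any stated axis lists; the generator
takes its axes from configuration, and the stated lists are the
default.)  Stored per cell are the *solute split fractions*
`φ_top = (1−s)·c_out_top` and `φ_bot = s·c_out_bot`, which sum to 1
exactly; interpolating the split (rather than the outlet concentrations)
makes solute conservation through lookups exact by construction.  A 0 %
bottom share is excluded: the corresponding steady state has an
`exp(λh)`-fold (~10¹⁰) bottom reservoir and an ill-conditioned linear
system — chambers whose single outflow leaves via the top port are
instead looked up at the 1 % axis minimum (a nearly closed bottom), and
their channel carries the conservative flow-weighted outlet mix.

**Topology.**  Chambers form a grid (rows = vertical position, columns =
flow direction).  Flow is strictly left-to-right; every channel connects
to the next column within one row of its source.  Each chamber has one
or two outflow channels (distinct targets) and at least one inflow
(several inflows mix flow-weighted); the generator first guarantees
every chamber an inflow, then caps out-degrees at two and adds second
outflows with probability 0.5.  Two-outflow chambers split their
throughflow with a bottom share drawn uniformly from [0.1, 0.9] (the
split distribution is an interpretation; nothing stronger is specified).

**Geometric port assignment.**  Channels attach to chamber outlets
according to the vertical geometry: a channel descending one row leaves
via the *bottom* outlet, one ascending a row via the *top* outlet;
same-row and boundary channels are assigned at random.  This preserves
the gravity-driven segregation of the species: strongly thermophoretic
solutes, enriched at chamber bottoms, consistently hand their excess to
lower rows and sink through the network, while weak solutes remain
relatively enriched above.  (With fully random ports the segregation —
and with it most of the network's selectivity — averages away: the
20×20/30-system weak-over-strong statistic drops by an order of
magnitude.)  A consequence of exact per-column solute conservation is
that depletion *along the flow direction* cannot occur in this model;
the separation manifests across rows.  `port_assignment="random"` is
retained for comparison.

**Statistics.**  The "maximum enrichment" of A over B is the median of
the ten largest per-chamber bottom-region concentration ratios, pooled
over all chambers of all systems of an ensemble (pooling matches the
all-chamber maximisation in the statistic's definition; a per-system
variant is a one-line change).  Ensemble errors are propagated by
redrawing each species' Soret coefficient from a Gaussian with its
random error, regenerating topologies, and repeating; failing systems
are excluded and counted.  ΔT is uniform across the network.

## Glycine-dimerization kinetics

The scheme — activation `Gly + TMP →(k1) GlyAct`, hydrolysis
`GlyAct →(k2) Gly`, dimerization `GlyAct + Gly →(k3) GlyGly`, TMP
hydrolysis `TMP →(k4) waste`, dimer hydrolysis `GlyGly →(k5) 2 Gly` — is
integrated as a stiff-capable ODE system.  Glycine units
`[Gly] + [GlyAct] + 2[GlyGly]` are conserved identically.  The
bimolecular rates k1 and k3 carry units M⁻¹s⁻¹ (required for dimensional
consistency of the bimolecular terms, although such rates are sometimes
printed as "Ms⁻¹").  The reference rate set (k1 = 1.0e-3 M⁻¹s⁻¹,
k2 = 1.1e-4 s⁻¹, k3 = 9.7e-5 M⁻¹s⁻¹, k4 = 3.5e-7 s⁻¹, k5 = 1.2e-6 s⁻¹,
fitted at 90 °C and initial pH 10.5) is applied without temperature
correction, exactly as in the source analysis; the temperature mismatch
between the 90 °C rate measurements and 25–45 °C chambers is inherited,
not resolved.

**Fitting.**  k4 comes from a separate TMP-only decay series, fitted in
log space (the natural residual under multiplicative noise; unbiased).
The remaining four rates are fitted simultaneously to the titration
(product after 16 h at 2 glycine × 9 TMP levels spanning three decades)
plus the 100 mM/100 mM time series to 120 h, in log-parameter space with
log-concentration residuals, multi-start (one central + seeded random
starts in broad bounds), with uncertainties from the residual covariance
and a condition-number warning for flat directions.  On noiseless
self-generated data all four rates are recovered to optimizer precision.

**Trace-concentration oracle.**  At trace concentrations the product
follows the closed form `GG(t) = R·(e^{−k4 t} − e^{−k5 t})/(k5 − k4)`
with `R = k1 k3 [G]² [T]₀ / k2` (quasi-steady activation; hydrolysis
factors retained — over 120 h they contribute ~30 % and cannot be
dropped).  The integrator matches this within 5 %; at 1 µM feeds the
120 h product is ~2.7e-16 M.

**Network coupling.**  Each chamber's bottom-region Gly and TMP
concentrations index a precomputed log-spaced batch-outcome grid
(default 1e-10–1 M, five points per decade, product recorded over 120 h)
by log-bilinear interpolation; the reaction is treated as a closed 120 h
batch because chamber relaxation times (10¹–10² h) exceed the reaction's
16 h completion.  Yields are `2c_GG/(2c_GG + c_Gly)`.  Out-of-grid
concentrations are clamped with a warning.

## Synthetic data

The generators emulate the statistical structure of the measurements:
fraction tables are produced by the forward transient model with a
uniform ±jitter/2 replicate temperature jitter (default 1.5 K, the
stated 1–2 K magnitude) and multiplicative lognormal noise (default 3 %;
detector integrals are positive with roughly proportional error);
reaction datasets integrate the ODEs at the standard design with
lognormal noise and triplicate structure.  They do *not* emulate
chromatographic artefacts, calibration nonlinearity, degradation, or
chamber-geometry irregularities — so passing round trips demonstrate
the correctness and identifiability of the pipelines under the assumed
noise model, not robustness to instrument systematics.

Solute presets: only two measured anchors are embedded
(S_T(3′,5′-cAMP) = 5.1e-3 ± 0.9e-3 1/K; S_T(TMP) ≈ 7e-3 1/K).  All other
preset values are synthetic stand-ins chosen once to span the observed
range (1.4e-3–7.5e-3 1/K) with the right qualitative ordering (glycine
weakest; aliphatic amino acids strongest), labelled as such in the
preset table, with stand-in random errors of 15 %.  Network statistics
computed from the presets reproduce reported headline values within
their error bands, but this is a consistency check of the mechanism, not
a per-species validation.

## Problem sizes used in the test suite

Chamber solves in tests use 16 × 80 to 32 × 160 cells (library defaults
40 × 200); the shared transfer table uses 2016 cells at 16 × 160; network
shape tests use 20 × 20 grids with 3-system sweeps, the headline
statistics 20 × 20 with 30 pooled systems, and the reaction grid three
points per decade.  These sizes were chosen so the full suite and the
acceptance script each complete in minutes on one CPU while every
documented tolerance is met with margin; the library defaults are
finer.

## Known limitations

* The thin-gap analytic flow omits end effects beyond a one-cell taper
  and any 3-D structure near real inlet channels.
* `S_T` is treated as temperature-independent within a run.
* The network model is steady-state only; start-up transients and
  temporal fluctuations are out of scope (per-chamber ΔT jitter exists
  as an option but is off by default).
* With the uniform [0.1, 0.9] split-ratio interpretation the absolute
  network-coupled yields at ΔT = 10 K reach ~1e-3 rather than the
  ~10 % reported for the corresponding full-scale analysis; the relative
  enhancement over ΔT = 0 (five orders of magnitude) and the shape of
  the yield–ΔT relation are reproduced.  Weak-species absolute
  enrichment is the quantity most sensitive to the unstated split
  distribution.
* GlyGlyGly and longer oligomers, pH dynamics, and speciation of the
  activated intermediate are outside the kinetic scheme.
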