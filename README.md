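# thermotrap

Modelling toolkit for **thermogravitational enrichment of dissolved
prebiotic compounds in heat-flow chambers and networks of rock cracks**.

Thin, water-filled rock fractures that carry a lateral heat flux act as
molecular traps: the temperature gradient across the gap drives both a
laminar convection roll and thermophoretic drift of each solute
(velocity `v_T = -∇T · S_T · D`, with Soret coefficient `S_T = D_T / D`).
Their interplay builds an exponential vertical concentration profile whose
strength differs between chemical species, so complex mixtures of amino
acids, nucleotides, 2-aminoazoles and polyphosphates are *selectively*
enriched and spatially separated — and networks of connected cracks
amplify the separation by orders of magnitude.  The package is aimed at
researchers in origins-of-life biophysics who want to simulate such
systems, infer thermophoretic parameters from fraction-resolved chamber
measurements, and couple the resulting concentrations to reaction
kinetics.

## What is inside

| module | contents |
| --- | --- |
| `thermotrap.water` | liquid-water property correlations (Kell density/expansivity, Vogel viscosity) |
| `thermotrap.physics` | domain types; the dimensionless group `q = ΔT·β·g·ρ·α³/(6·η·D)` and the closed-form steady profile `c(y) = exp(-(q/120)/(1+q²/10080)·S_T·ΔT·y/α)` |
| `thermotrap.solver` | 2-D finite-volume drift–diffusion solver with the analytic thin-gap convection roll and Poiseuille throughflow |
| `thermotrap.transfer` | precomputed single-chamber response tables over (ΔT, D, S_T, Q_in, bottom-outflow share), with conservative multilinear interpolation |
| `thermotrap.soret` | fraction normalization, pairwise/pool enrichment statistics, Soret-coefficient fitting, systematic/random replicate-error decomposition |
| `thermotrap.network` | stochastic crack-network generator, solvent flow solving, column-wise concentration propagation, median-of-ten-maxima enrichment statistic, Monte-Carlo ensembles |
| `thermotrap.reaction` | TMP-driven glycine-dimerization kinetics (rates k1–k5), rate fitting, reaction lookup grids, network–reaction coupling |
| `thermotrap.synthetic` | seeded generators for every input the pipeline consumes, plus labelled solute presets |
| `thermotrap.config` | strict YAML run configuration and manifest-based result writing |

The public face is the importable API plus the narrative scripts in
`examples/`; see `docs/methods.md` for the modelling choices and their
justification.

## Worked example

`examples/single_chamber_accumulation.py` models the standard measurement
chamber (50 mm tall, 170 µm gap, walls at 25 °C and 40 °C) holding a
nucleotide-like solute with `S_T = 5.1e-3 1/K`:

```
thermogravitational group q = 36.8  (optimal would be ~100.4)
steady bottom/top concentration ratio: 422-fold
log-slope: solver -121.6 1/m vs closed form -121.6 1/m
fraction means after 18 h (top -> bottom): [0.375 0.722 0.999 1.905]
The bottom quarter holds 5.1x the top quarter's concentration — the
measurable enrichment of an 18 h experiment, still far from the
steady-state ratio above.
```

The numerical steady state reproduces the closed-form accumulation slope
to better than a tenth of a per cent; the 18 h transient shows what an
experiment of realistic duration actually measures (a ~5-fold
bottom-to-top fraction contrast rather than the 422-fold asymptotic point
ratio), which is why the Soret-fitting pipeline matches transient — not
steady — fraction means.

The other examples build on this: `fit_soret_coefficients.py` round-trips
Soret coefficients through noisy triplicate fraction tables and splits
the replicate error into its systematic (temperature-jitter) and random
parts; `crack_network_enrichment.py` propagates a glycine/isoleucine-like
pair through a 12×12 crack network and prints the enrichment statistics
and the vertical segregation of the two species;
`glycine_dimerization.py` recovers the five dimerization rate constants
from synthetic titration + time-series data and integrates batch
outcomes from femtomolar to percent-level yields.

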