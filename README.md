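# monodom

Spatial dynamics of monodominant forest patches from repeated stem
censuses.

Some tropical rainforests are dominated by a single canopy species —
*Gilbertiodendron dewevrei* in the Congo basin is the classic case —
forming near-homogeneous patches embedded in otherwise species-rich
forest. Whether such patches are advancing into the surrounding mixed
forest, and how fast, is a question about boundaries that ordinary
stand-level statistics cannot answer. `monodom` answers it from
ForestGEO-style stem tables (tag, species, quadrat, local x/y, DBH,
status) for two or more censuses of a rectangular plot, using three
complementary measurements:

1. **Area-weighted mean radius of gyration.** Basal area (BA) is
   rasterised to 1 m² cells, edge-corrected by reflection, converted to
   m² BA ha⁻¹ with a one-hectare circular focal sum, and thresholded
   into patches. The radius of gyration of patch *p* with cells *r* is

       rog(p) = (1/z) Σ_r ||x_r − x̄_p||,

   and the area-weighted mean Σ z_p·rog(p) / Σ z_p (the correlation
   length) summarises landscape-scale patch extent; its change per year
   is an expansion rate in m yr⁻¹.

2. **Boundary-vertex movement regression.** Threshold isolines are
   polygonised, filtered (≥ 300 m², ≥ 30 m isolation) and tracked across
   censuses; later-census boundary vertices are matched to nearest
   earlier vertices under a reuse cap, grouped into cardinal quadrants
   about the earlier centroid, and each group's coordinate Y is fitted by

       Y = β₀ + β₁·year + ε,   Var(ε) = σ² δ²_s   (δ₁ = 1),

   with one residual variance per census stratum *s*; β₁ is the
   boundary movement rate in m yr⁻¹, with BCa bootstrap intervals and
   permutation validation of the pairing.

3. **Vector fields of BA change.** Gaussian-kernel BA intensity
   surfaces (25 m bandwidth, mass-renormalising boundary correction)
   are differenced between censuses; Horn slope/aspect of the
   difference gives a magnitude and direction of change per cell, and a
   pixel bootstrap gives the plot-level change in m² BA ha⁻¹.

A synthetic stem-map generator with imposed, analytically-known boundary
dynamics makes every stage testable without access to field data. See
`docs/methods.md` for models, assumptions, and limitations.

## Worked example

Generate a synthetic landscape whose single patch boundary advances at
0.25 m yr⁻¹ and recover the dynamics:

```python
from monodom import (SimulationConfig, PatchSpec, simulate, analyze_site)

cfg = SimulationConfig(patches=[PatchSpec(rate=0.25)], seed=11)
pair = simulate(cfg)
report = analyze_site(pair.census1, pair.census3, cfg.plot,
                      cfg.target_species, threshold=cfg.threshold,
                      seed=11, n_boot=1000, n_perm=1000)
print(round(report["gyration"]["boundary_advance_disc_estimate_m_yr"], 3))
print(round(report["radial_advance_estimate_m_yr"], 3))
```

prints

```
0.216
0.212
```

— the gyration-based and boundary-regression-based estimates of the
imposed 0.25 m yr⁻¹ advance (both slightly shrunk by nearest-vertex
matching; the raw per-quadrant rates, bootstrap intervals and
permutation p-values are in `report["movement"]`).

The published per-quadrant movement rates ship with the package, and the
cross-table summaries can be reproduced from the command line:

```
$ monodom summarize
mean N: +0.35 m/yr
mean E: +0.09 m/yr
mean S: +0.40 m/yr
mean W: +0.39 m/yr
overall: +0.31 ± 0.30 m/yr
global mean (a): 1.22 ± 0.54 m/yr
global mean (b): 1.06 ± 0.56 m/yr
```

The oriented mean of all twenty quadrant models is +0.31 m yr⁻¹
(t-based 95% margin ±0.30): monodominant boundaries advance, slowly.
The global means place that alongside published forest-advance rates
from other African and American ecotones (set *a*: all flagged studies;
set *b*: omitting two structurally dissimilar ones).

Other CLI stages: `monodom simulate | rasterize | delineate | gyration |
boundary | vectorfield | run-all` (see `--help`; `run-all` drives the
whole pipeline from a YAML config with per-site thresholds and reuse
caps).

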