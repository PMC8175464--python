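# vesselmorph

Skeleton morphometry of traced 3D centerline networks — brain capillaries
and neurites in particular.

Manual tracing of micro-CT or nanotomography volumes produces
Cartesian-coordinate models of tubular structures: spherical nodes (center +
outer radius, in µm) connected by edges into a network. `vesselmorph` turns
such models into quantitative structure: diameter distributions by length
fraction, discrete curvature and torsion profiles, length-weighted per-sample
summaries, and cohort-level correlation and variance analyses of the kind
used to compare capillary and neurite geometry across cases and brain areas.

## What it computes

**Segments.** A skeleton graph (SWC for trees, a JSON dialect for networks
with loops) is partitioned into maximal unbranched paths — "vessel
segments" — whose interior nodes have degree 2. Total vessel length is the
sum of Euclidean edge lengths.

**Geometry.** Along each segment (resampled at a uniform 1 µm arc step by
default):

- curvature κᵢ is the Menger curvature of consecutive point triples,
  κ = 4·Area(P₋,P₀,P₊)/(|P₋P₀|·|P₀P₊|·|P₋P₊|) — the reciprocal of the radius
  of the circle through the three points, exact on circular arcs;
- torsion τᵢ is estimated from consecutive quadruples as the rotation rate
  of the binormal, signed by the handedness of the chord triple
  (right-handed spiral → τ > 0); for a helix of radius r and pitch parameter
  c the estimates converge to κ = r/(r²+c²), τ = c/(r²+c²);
- each point carries an arc-length weight (half the sum of its incident
  chords), so means weighted by these recover "weighting by vessel length".

**Morphometry.** The diameter distribution assigns each point's arc-length
weight to the 0.4 µm bin containing its local outer diameter and normalizes
by total length. Segments with length-weighted mean outer diameter < 15 µm
are classified as capillaries. Length-weighted means come with standard
errors from the ratio-variance (Cochran ratio-estimator) approximation,
which reduces to s/√n under equal weights.

**Cohort analysis.** Given per-sample capillary summaries joined with
per-sample neurite summaries (one row per sample × brain area), the report
contains Spearman rank correlations (capillary vs neurite curvature;
capillary diameter vs neurite thickness radius; exact permutation p-values
below n = 10, t-approximation above), Bartlett's test of between-area
variance of mean capillary curvature, an OLS regression line, and a
slope-difference (interaction) test between diagnostic groups — each flagged
at α = 0.05.

**Synthetic data.** Since traced capillary datasets are rarely released,
`vesselmorph.synthetic` generates analytically verifiable fixtures (circles,
helices with closed-form κ/τ) and capillary-like networks: correlated random
walks whose von Mises–Fisher direction persistence is calibrated to a target
mean curvature (0.02–0.04 µm⁻¹ range), log-normal diameters peaking in the
7–9 µm capillary band, achiral turn azimuths (zero-mean torsion), and full
case/control cohorts with a planted capillary–neurite curvature association.

## Worked example

```python
from vesselmorph import (make_circle_graph, summarize_sample,
                         make_cohort, CohortSpec, run_fig4_analysis)

# a closed circular capillary loop, radius 27 um, outer diameter 8 um
s = summarize_sample(make_circle_graph(27.0, step=1.0, diameter=8.0))
print(f"mean capillary curvature: {s.mean_capillary_curvature:.4f} um^-1")
print(f"mean capillary diameter:  {s.mean_capillary_diameter_um:.2f} um")

# a synthetic cohort: 8 cases x 2 areas, planted curvature association
cohort, _ = make_cohort(CohortSpec(seed=1))
print(run_fig4_analysis(cohort).to_text())
```

prints

```
mean capillary curvature: 0.0370 um^-1
mean capillary diameter:  8.00 um
Cohort analysis (alpha = 0.05 per test; no multiple-testing correction)
  rows: 16
  capillary curvature vs neurite curvature (Spearman rho): estimate=0.6794, p=0.003793, n=16 (significant at alpha=0.05)
  capillary diameter vs neurite thickness radius (Spearman rho): estimate=0.2118, p=0.4311, n=16 (not significant at alpha=0.05)
  area variance of capillary curvature (BA22 vs BA24, Bartlett): estimate=0.1165, p=0.7329, n=16 (not significant at alpha=0.05)
  regression (capillary vs neurite curvature): slope=0.02171, intercept=0.003863
  slope difference (schizophrenia vs control): estimate=-0.0154, p=0.3742, n=16 (not significant at alpha=0.05)
```

The 0.0370 µm⁻¹ mean curvature is the reciprocal of the 27 µm loop radius —
the curvature↔radius pairing the estimator must reproduce exactly. In the
cohort, the planted curvature association is detected while the
independently drawn diameters show none, the qualitative pattern such a
case/control analysis is designed to resolve.

The same pipeline is available from the shell:

```sh
vesselmorph simulate spec.json -o data/     # synthetic networks or cohorts
vesselmorph summarize data/networks/*.json -o out/
vesselmorph distribution data/networks/*.json -o out/
vesselmorph correlate out/summary.csv neurites.csv -o report/
vesselmorph convert model.swc model.json
```

Every run writes a log of all result-affecting parameters next to its
outputs.

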