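# Methods

## Data model

A traced model is an undirected graph of spherical nodes — 3D center and
outer radius, both in physical µm — connected by straight edges. The outer
radius includes the vessel wall (what a Golgi-type stain delineates), so
"diameter" throughout means outer diameter; no unit conversion is applied
anywhere (voxel-to-µm scaling is a CLI option applied at load). SWC covers
forest-shaped models; because anastomosing vessel networks can contain
loops, which SWC's child→parent records cannot encode, a versioned JSON
graph dialect with explicit node and edge lists is the general format, and
both round-trip losslessly within their domains. Edges of zero length
(coincident consecutive centers, occasionally produced by manual tracing)
are contracted at load with a warning — they would otherwise produce
zero-length chords and undefined curvature.

Analysis operates on *unbranched paths*: maximal chains whose interior
nodes have degree 2. The decomposition partitions the edge set exactly;
branch nodes are carried as endpoints by each incident path so paths stay
geometrically continuous through junctions without double-counting edges,
and no curvature or torsion is computed across a junction (the Frenet frame
is undefined at a bifurcation). Isolated cycles become closed paths with a
deterministic start (lowest node id) and orientation (toward the lower-id
neighbor), and their wrap-around geometry is computed cyclically, so a
closed loop has no endpoint artifacts.

## Curvature and torsion estimators

Curvature is the Menger curvature of consecutive point triples:
κ = 4A/(abc), the reciprocal circumradius of the triangle. This matches the
definition of curvature as the reciprocal of the local curve radius and is
*exact* for concyclic samples at any spacing — the property the circular
fixtures test to 10⁻¹² — with collinear triples giving κ = 0.

Torsion uses consecutive quadruples: the binormals of the two overlapping
triples are b₁ = e₁×e₂ and b₂ = e₂×e₃ (eᵢ the chord vectors); the torsion
magnitude is the angle between b₁ and b₂ divided by the middle chord length
|e₂|, and the sign is that of (e₁×e₂)·e₃, making a right-handed spiral
positive and mirror reflection negate the profile. If either triple is
collinear the binormal is undefined and τ = 0 by convention; a coplanar
quadruple gives τ = 0 naturally. On helices both estimators converge to the
closed forms r/(r²+c²) and c/(r²+c²) at second order in the step (verified
by step-halving), and are inside 1% at steps ≤ 0.05·r.

Both estimators are scale-covariant (coordinates ×a ⇒ κ, τ ×1/a) and
invariant under rigid motions; these are property-tested.

## Length weighting

Each sample point carries a Voronoi arc-length weight — half the sum of its
incident chord lengths — so weights sum exactly to the path's arc length.
All means (diameter, curvature, torsion) are weighted by these, which
realizes "weighting by vessel length" at point granularity: a 2 mm segment
influences a sample mean 10× more than a 0.2 mm one, regardless of node
counts. Curvature values are weighted by their center point's weight;
torsion values by the weight of the first interior point of their quadruple.

The standard error of a weighted mean x̄_w = Σwx/Σw uses the ratio-variance
(Cochran ratio-estimator) approximation, treating numerator and denominator
as jointly random:

    SE² = n/((n−1)(Σw)²) · [ Σ(wᵢxᵢ − w̄x̄_w)²
                             − 2x̄_w Σ(wᵢ−w̄)(wᵢxᵢ − w̄x̄_w)
                             + x̄_w² Σ(wᵢ−w̄)² ]

Under equal weights this reduces algebraically to s/√n (asserted to 10⁻¹²).
Here n is the number of weighted points; users wanting per-segment
aggregation can average per path first and pass path sums as weights. A
single observation returns SE = NaN (undefined, not zero).

## Resampling and smoothing

Manual node spacing is irregular, which biases finite-difference estimators.
Profiles are therefore computed by default on the polyline resampled at a
uniform 1.0 µm arc step — near the µm-scale spatial resolution of the
source imagery, below typical capillary curvature radii (25–50 µm) — with
endpoints preserved and radii interpolated linearly in arc length. A raw-node
mode (`resample_step_um=None` / `--resample-step 0`) is available. Arc
length is preserved to within one step on smooth curves; note that
resampling a jagged polyline shortens it (corner cutting), which is why
*total* vessel length is always reported from the raw edges. No coordinate
smoothing is applied by default — smoothing systematically lowers curvature
— but an opt-in moving-average window (in µm) exists for noisy traces.

## Morphometry conventions

- Diameter bins are half-open [k·0.4, (k+1)·0.4) µm starting at 0; a value
  exactly on an edge belongs to the upper bin (binned via `np.digitize`, so
  the edge case is deterministic in floating point). Bin width is
  configurable.
- The distribution uses *local* (per-point) diameters by default, so a
  tapering vessel spreads across bins; a per-segment-mean mode
  (`local_diameters=False`) is provided for comparison.
- A segment is a capillary iff its length-weighted mean outer diameter is
  strictly < 15 µm (configurable). The rule is per segment, not per point.
- Capillary curvature/torsion means pool point estimates across all
  capillary segments of a sample, weighted by arc length. Samples with no
  capillary segments report NaN capillary fields (absent, not zero).
- Both the signed mean torsion and the mean |τ| are reported: the signed
  mean tests chirality (zero for achiral anatomy), |τ| measures
  non-planarity regardless of handedness.

## Cohort analysis

One row per sample × brain area, joining capillary summaries with neurite
summaries. Spearman ρ is computed on mid-ranks; the two-sided p-value uses
the exact permutation distribution for n < 10 and the t-approximation
t = ρ√((n−2)/(1−ρ²)) otherwise (n = 16, the design size here, is well inside
the approximation's range). Bartlett's test (scipy) compares between-area
variances of mean capillary curvature; it requires ≥ 2 values and nonzero
variance per group. The regression line is OLS on all rows (a per-group fit
is a flag away), and the group slope comparison is an OLS interaction
t-test, reported descriptively. Significance is α = 0.05 per test with no
multiple-testing correction, matching how such analyses are reported in the
source field; the report says so explicitly. Reports are deterministic:
identical tables give byte-identical text.

## Synthetic generator

The generator emulates the statistical structure of traced Golgi-stained
capillary networks, not their biology:

- **Centerlines** are correlated random walks with fixed step (default
  1 µm): each direction is drawn from a von Mises–Fisher distribution about
  the previous one. The concentration ("persistence") maps monotonically to
  realized mean curvature; the mapping depends on step length, so it is
  calibrated empirically and shipped as a sweep table
  (`_persistence_sweep.json`, regenerable via
  `persistence_curvature_sweep`), inverted by log-log interpolation.
  Calibration recovers targets in the 0.021–0.037 µm⁻¹ range within a few
  percent (tested at 10%).
- **Turn azimuths** are uniform in the parallel-transported normal plane,
  making the walk achiral — the length-weighted mean signed torsion is zero
  in expectation, matching the symmetric zero-centered torsion profiles of
  real capillaries. A `torsion_bias` drifts the azimuth to plant handedness
  of either sign.
- **Diameters** are log-normal per path (median 8 µm, σ_log 0.1) with a
  small smooth taper, which places the modal 0.4 µm bin of the
  length-fraction distribution in the 7–9 µm capillary band without
  asserting the true anatomical distribution.
- **Path lengths** are gamma-distributed (shape 3, mean 150 µm by default);
  real per-sample length distributions are unpublished, so this is an
  assumption chosen to give many segments of tens-to-hundreds of µm.
  Optional branching roots a path at an interior node of an earlier one,
  producing degree-3 junctions.
- **Cohorts** (default 8 cases × 2 areas = 16 rows): per row, neurite
  curvature x ~ U(0.8, 1.6) µm⁻¹ (the tortuous-neurite regime), target
  capillary curvature 0.005 + 0.02·x + N(0, 0.0057) µm⁻¹, realized by
  generating and summarizing an actual network at the calibrated
  persistence; capillary diameter and neurite thickness radius
  (N(0.30, 0.05) µm) are independent of everything else. These constants
  plant a population Spearman correlation of ≈ 0.63 between the two
  curvatures — the size of association the analysis is meant to detect —
  while leaving the diameter pair at the null. An `area_spread_ratio`
  multiplies the noise SD in the first area to emulate a wider between-case
  variance there (1 = equal variances).

What the generator does **not** emulate: Golgi-staining sparsity beyond
per-path inclusion, image noise and tracing error, vessel hierarchies
(arterioles/venules beyond the log-normal tail), spatially structured
vascular topology, or real neurite geometry (neurite summaries are drawn,
not traced). Passing tests therefore demonstrate correctness of the
estimators and calibration of the statistics under known ground truth — not
anatomical realism of any particular dataset.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; same spec + seed ⇒ bit-identical outputs.
Default validation sizes: networks of 10–70 paths (10³–10⁵ points),
cohort simulations of 200 replicates at n = 16, and 1000-replicate
calibration of Bartlett's test — sizes at which binomial error on the
checked rates is a few percent. At the planted effect (population ρ ≈ 0.63)
and n = 16, the two-sided α = 0.05 Spearman test has power ≈ 0.75; detection
frequencies in that range are the expected behavior at this design size,
not an estimator defect (a single study reporting p < 0.05 at this effect
size is one draw from that distribution).

## Known limitations

- Menger curvature is unbiased on circles but, like all finite-difference
  estimators, inflates under coordinate noise at fine steps; the default
  1 µm step trades this against feature resolution, and smoothing is
  opt-in.
- The discrete torsion magnitude is noisy on rough (non-differentiable)
  curves such as the synthetic random walks: per-point |τ| is large even
  when the signed mean is zero. Comparisons should use the signed mean (or
  distributions), as done here.
- The SWC writer re-roots each tree at its lowest node id; node ids and
  record order are preserved, parent direction is not guaranteed to match
  the input's.
- The ratio-variance SE treats points as independent; spatial correlation
  along a vessel makes it an underestimate of sampling error for small
  numbers of long segments.
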