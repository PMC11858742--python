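# Methods

This note documents the models and procedures implemented in `paleodark`,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Data model and partition

The analytical unit is the *occurrence*: one taxon at one collection
(locality + horizon).  Canonical tables carry taxonomy (species/genus/
family plus the finest identified `rank`), modern and palaeo-coordinates,
an interval age `[min_ma, max_ma]` in Ma, lithology ∈ {carbonate,
siliciclastic, unknown}, grain size, found/housed country labels, a
specimen count, and three provenance booleans.  Invariants are enforced at
ingest (`validate_occurrences`): `max_ma > min_ma ≥ 0`, coordinates in
range, `in_pbdb ⇒ in_published`, and `in_dark xor in_published` — "dark"
means museum-*only*, so dark and published are mutually exclusive by
definition.  Rows violating an invariant are dropped with row- and
field-indexed diagnostics rather than silently coerced.

**Deduplication** collapses repeat appearances of the same taxon in the
same collection, keyed by the *finest available* name (species, else
genus, else family) — the most conservative reading of a rank-ambiguous
rule.  Specimen counts are summed and provenance flags OR-combined; a
merged record that is published anywhere ceases to be dark, preserving the
xor invariant.

**Majority time binning** assigns each occurrence to the bin holding the
largest share of its age interval; exact ties go to the older bin, fixed
by taking the first maximum over bins ordered old→young.  A `strict` mode
additionally discards assignments with ≤ 50% overlap (off by default; the
plain greatest-overlap rule keeps more data and the choice is surfaced as
a flag rather than hidden).  Binning is deterministic and idempotent, and
per-bin counts plus the unassigned count always reconcile with the input.
Packaged bin tables cover the Palaeozoic (538.8–251.902 Ma) at stage level
and at sub-period level, the latter splitting the Carboniferous into
Mississippian and Pennsylvanian.

## Synthetic generator

The generator exists so that every estimator has a known right answer.
Each taxon's true geographic range is a **spherical cap** (centre +
radius in km) — caps rather than polygons because the cap area
`2πR²(1 − cos(r/R))`, `R = 6371.0088 km`, is closed-form, which makes
hull-recovery tests exact.  True temporal ranges are `[FAD, LAD]`
intervals; true substrate preference is a carbonate probability.

Occurrences are drawn through two channels (dark, published), each with:
sampling intensity (Poisson per-taxon counts scaled by an abundance
weight), lithology/grain-size/taphonomic-grade distributions, a temporal
weighting exponent *e* (relative position `r = u^e`, `u ~ U(0,1)`; *e* > 1
concentrates occurrences toward the old end — "bottom-weighted"), a
spatial `radius_fraction` restricting the channel to an inner cap, rank
identification probabilities, and country pools with a domestic
(found = housed) probability.  The PBDB channel is a Bernoulli subsample
of published rows.  Collections are formed by pooling occurrences within
5°/10-Myr cells, ~3 occurrences per collection, giving realistic
incidence-frequency spread for rarefaction.

Default parameters are the study conditions the package is sized for: a
combined record of ~2223 occurrences split ~976 dark / ~1247 published /
~590 PBDB; a dark channel ~85% carbonate-hosted, coarser-grained, poorer
taphonomic grades, ~40% genus-level identifications and bottom-weighted
(*e* = 2.2); a published channel ~62% carbonate and temporally even.
Channel probabilities not pinned by those conditions (grade distributions,
country weights, rank mixes for the published channel) were chosen once as
field-plausible values and are not tuned.

What the generator does *not* emulate: plate motion (palaeocoordinates are
drawn directly; real analyses consume externally rotated coordinates),
spatially autocorrelated sampling within ranges, taxonomic error, or
non-stationary preservation through time.  Passing tests therefore
demonstrate estimator correctness under known truth, not robustness to
every real-data pathology.

## Geographic ranges

Hulls are **spherical convex hulls**: points are gnomonically projected
onto the tangent plane at their vector mean — gnomonic projection maps
great circles to straight lines, so the planar hull of the projection *is*
the spherical hull — and the hull cycle's area is computed by fan
triangulation with l'Huilier's spherical excess on the authalic radius.
This construction is intrinsic to the sphere: it is indifferent to the
antimeridian and monotone under point-set containment (subset hull area ≤
total hull area), which a hull built in raw lon/lat coordinates is not for
large ranges.  Point clouds not contained in an open hemisphere have no
spherical convex hull; they are flagged `wide_span` and measured with a
longitude-frame planar fallback.  Fewer than three distinct or collinear
points give area 0 and are excluded from ratio metrics (counted, not
imputed).  All reported range metrics are area *ratios*, so the area
convention cancels; internal consistency is what matters.

Occupancy grids index cells by `floor(coordinate/resolution)` (SW-corner
labels) after normalising longitudes to [−180, 180).  "Mean of the
latitudinal range" is taken as the interval midpoint; the occurrence-mean
latitude is emitted alongside as a sensitivity column.  The latitudinal
width added by dark data is normalised both by the total width and by the
remaining datasets' width, since either convention is defensible.

## Temporal ranges

FAD/LAD are bin-boundary based (oldest bound of the oldest occupied bin,
youngest of the youngest): occurrences carry interval ages, so point-age
conventions would manufacture precision.  Subset ranges are therefore
always contained in the combined range, and overlap% reduces to the
subset's share of the total duration.  The guard against temporal
uncertainty — restricting to taxa found in at most `max_bins_filter = 2`
bins — is a configurable taxon filter (disable with `None`); it is read as
"taxa spanning ≤ 2 bins", the more natural of the two possible readings,
and the filter is exposed so the other can be examined.  Occurrence
positions use bin midpoints scaled into [0, 1] from the FAD end; single-bin
taxa are excluded because the convention pins their every occurrence to
r = 0.5.

## Coverage-based rarefaction

Incidence frequencies `Y_i` count the collections containing taxon *i*
among `T` collections; `U = ΣY_i`, `Q1`/`Q2` are singleton/doubleton
counts.  Reference-sample coverage is
`Ĉ(T) = 1 − (Q1/U)·[(T−1)Q1/((T−1)Q1 + 2Q2)]`.  Interpolated richness is
the exact expectation `S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)`;
extrapolation uses the Chao2 undetected-richness estimate
`Q̂0 = ((T−1)/T)·Q1²/(2Q2)` (fallback `((T−1)/T)·Q1(Q1−1)/(2(Q2+1))` when
`Q2 = 0`).  Coverage is made continuous in *t* with gamma-function
binomials on [1, T−1], a linear bridge over [T−1, T] (the rarefied formula
is undefined past T−1; its value there, `1 − Q1/U`, is bridged to `Ĉ(T)`),
and the geometric extrapolation form beyond T; the quorum inversion is a
200-step bisection, giving round-trips `Ĉ(t*(q)) = q` to 1e−6.
Extrapolation is capped at 2T (flagged); bins with `T < 3` or all-singleton
incidences, and quorums unreachable within the cap, are reported as
*missing points* rather than estimated — sparse datasets resolve few
points, they do not gain fabricated ones.  Default quorums are
{0.4, 0.5, 0.6}.  Richness uncertainty (bootstrap CIs) is deliberately out
of scope.

## Substrate affinity

`RA = k/n − π` per family × interval × dataset, with π the carbonate
fraction of the combined dataset's lithology-known occurrences in the same
interval (pluggable reference pool).  SRA is the Monte-Carlo z-score of RA
against `k* ~ Binomial(n, π)` with `B = 5000` draws by default, seeded and
reproducible.  This operationalisation satisfies the statistic's defining
properties — sign tracks the direction of affinity, zero means no
preference, and null data score mean ≈ 0, sd ≈ 1 (verified over 5000
simulated null families) — which is how the implementation is validated.
Families with `n < 5` in an interval are withheld, and intervals with
π ∈ {0, 1} are flagged unanalysable (no binomial null exists).  Affinity
runs at the series/sub-period level, where per-family counts are usable.

## GLS-AR(1) and model selection

The response is raw per-bin genus richness (coverage-standardised richness
resolves too few points at these sample sizes; a log-response switch
exists but defaults off).  Covariates are log-normalised — natural log for
strictly positive series, log1p where zeros occur (recorded per series),
error on negatives; "log-normalised" is read as log-transform only, with
an optional standardise flag.  Bins missing any covariate are dropped
listwise and counted.

For fixed ρ the AR(1) model is whitened (first observation scaled by
√(1−ρ²), then quasi-differences), β and the innovation variance σ² are
profiled in closed form, and the *exact* Gaussian log-likelihood
(including the ½·log(1−ρ²) Jacobian term) is maximised over ρ with a
41-point grid plus bounded refinement — the grid guards against local
optima.  Estimation is ML, not REML, so AICc is comparable across models
with different fixed effects.  `df = k` counts fixed effects (incl.
intercept) + ρ + σ, making the intercept-only model df = 3;
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, requiring `n ≥ k + 2`.  `dredge`
enumerates all 2^p covariate subsets (guarded at p ≤ 12), ranks by AICc,
and breaks ties toward fewer parameters then lexical order, so covariate
input order affects nothing but tie display.

## Orchestration and reproducibility

`run_pipeline` executes ingest → composition → biogeography → latitudinal
→ temporal → diversity → affinity → drivers, writing one tidy CSV set per
stage and a JSON manifest with package version, seed, per-stage outputs
and row accounting (read, rejected, geo-filtered, deduplicated,
bin-unassigned, per-dataset sizes).  A single seed feeds every stochastic
stage; identical config + seed reproduces outputs byte-for-byte (CSV
floats are formatted, collection identifiers use a process-independent
hash).  A stage failure aborts with a stage-tagged error, leaves completed
outputs in place and writes a `FAILED` marker.  The geographic filter
offers `global` and a `north_america` bounding box (−170…−50°E, 5…85°N).

## Problem sizes used in validation

Calibrations run at sizes chosen to keep Monte-Carlo error well below the
tolerances they check: rarefaction vs 10,000 brute-force subsamples on
random 50-collection incidence matrices; SRA null calibration over 5000
simulated families (n = 30, π = 0.6); 500 randomised hull-geometry cases
within hemispheric clouds; 100–200 GLS replicates at n = 200 for ρ
recovery; and a 50-taxon, 200-occurrences-per-channel scenario for the
end-to-end recovery of a configured 35% dark-data area contribution
(published channel restricted to the inner cap with √0.65 of the radius;
truth recomputed analytically per taxon).  Finite point samples
under-cover both subset and total hulls, so recovered added-area means
carry a residual bias of a percentage point or two — the end-to-end check
budgets 5 points for bias plus Monte-Carlo error.

## Known limitations

- No plate-rotation model: palaeocoordinate quality is the caller's
  responsibility.
- Clouds wider than a hemisphere have no spherical convex hull; the
  planar fallback is flagged but approximate.
- SRA's Monte-Carlo null matches the statistic's defining properties but
  has no external numerical reference to compare against at desk scale.
- No abundance-based rarefaction, richness CIs, GAMs, mixed models or
  multi-lag ARMA error structures.
- Real published datasets embed georeferencing and taxonomic-vetting
  errors that the validation scenarios do not model.
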