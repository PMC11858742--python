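# paleodark

**What happens to macroevolutionary inference when museum "dark data" —
fossil specimens sitting in collections but absent from the published
literature and from online databases — are added to the record?**

`paleodark` is an analysis package for quantifying that question on fossil
occurrence data.  It compares four datasets built from provenance flags on
each occurrence:

| dataset | contents |
|---|---|
| **A** | dark data: museum-only, unpublished occurrences |
| **B** | the published record |
| **C** | the database-entered subset of B (e.g. PBDB records), C ⊆ B |
| **D** | the combined record, D = A ∪ B with A ∩ B = ∅ |

and measures, stage by stage, how much A changes what D looks like:

- **Composition** — lithology, grain size, taxonomic rank and taphonomic
  grade proportions per dataset; chi-squared / Kruskal–Wallis (with
  ε² = H/(n−1) effect sizes) / Wilcoxon rank-sum tests; the
  domestic-vs-foreign repository split used to assess "parachute science".
- **Biogeography** — 1° grid-cell occupancy with unique-cell contributions;
  per-taxon geographic range as the spherical convex hull of
  palaeocoordinates, with overlap% = 100·Area(S)/Area(D) and
  added% = 100·(Area(D) − Area(D∖S))/Area(D); latitudinal widths,
  interval overlaps and midpoint shifts.
- **Temporal ranges** — bin-boundary FAD/LAD per taxon and dataset,
  overlap/added-time percentages, and the within-range position
  r ∈ [0, 1] of each occurrence (r = 0 at the FAD end), which exposes
  "bottom-weighted" sampling channels.
- **Diversity** — raw per-bin richness and collection counts; Good's u;
  coverage-based rarefaction over collection-incidence frequencies,
  Ĉ(T) = 1 − (Q1/U)·[(T−1)Q1/((T−1)Q1 + 2Q2)], inverted by bisection so
  richness is compared at fixed coverage quorums (0.4/0.5/0.6), with
  Chao2-based extrapolation capped at 2T; Spearman correlations with
  Benjamini–Hochberg adjustment.
- **Substrate affinity (SRA)** — per family and interval, the excess
  carbonate proportion RA = k/n − π standardised against a
  Binomial(n, π) Monte-Carlo null; positive SRA ⇒ carbonate affinity.
- **Diversity drivers** — GLS regression with AR(1) errors fitted by exact
  maximum likelihood (whitening + profiled β, σ; ρ optimised on (−1, 1)),
  every covariate subset enumerated and ranked by
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), intercept-only df = 3.

Real palaeocoordinates are consumed as inputs (or supplied through a
rotation callback); no plate-rotation model is implemented.  A synthetic
generator (`paleodark.synthetic`) supplies occurrence datasets with known
true ranges, durations and affinities through channel configurations with
controllable biases, so every estimator above can be validated against
ground truth.

## Worked example

```python
import paleodark as pdk

occ, specimens, truth = pdk.simulate(seed=1)          # default conditions
occ = pdk.deduplicate(occ)
binned = pdk.assign_bins(occ, pdk.palaeozoic_stages())  # majority rule
part = pdk.partition(binned)
print(part.sizes)

from paleodark.temporal import occurrence_positions
pos = occurrence_positions(part, rank="genus")
print(pos.groupby("dataset")["r"].mean().round(2))
```

prints

```
{'A': 1008, 'B': 1222, 'C': 587, 'D': 2230}
dataset
A    0.37
B    0.52
C    0.52
```

— a combined record of 2230 occurrences split into 1008 museum-only and
1222 published (587 of those database-entered), and a dark channel whose
occurrences sit markedly nearer the old end of their taxa's ranges
(mean r 0.37 vs 0.52): the configured bottom-weighting, recovered by the
temporal-position analysis.

The numbered scripts under `analysis/` run the full comparison and write
tidy tables under `results/`:

```sh
python analysis/01_simulate.py      # synthetic study dataset
python analysis/02_composition.py   # ... through 07_drivers.py
```

`paleodark.pipeline.run_pipeline(AnalysisConfig(...))` runs every stage on
any canonical occurrence CSV and writes per-stage outputs plus a manifest
with seed and row accounting; identical config + seed reproduces all
outputs byte-for-byte.

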