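# paleomorph

Landmark-based geometric morphometrics for reconstructing trait
diversification from fossil assemblages — built around the kind of record
left by the Lake Victoria haplochromine cichlid radiation, where oral-jaw
tooth fossils from dated lake-sediment cores can be compared against the
teeth of the modern radiation's 18 trophic guilds to ask *when* each feeding
specialization emerged and *how fast* morphological variety accumulated.

The package is aimed at evolutionary biologists and palaeoecologists working
with 2-D landmark data (tpsDig2-style TPS files): it covers the full chain
from digitized coordinates to disparity-through-time statistics and
ancestral-to-guild divergence trajectories, plus a synthetic-radiation
generator with planted, recoverable structure so every stage can be validated
without real fossils.

## What it computes

- **Superimposition.** Generalized Procrustes analysis (translation, unit
  centroid-size scaling, rotation; reflections excluded) of the modern
  reference; new specimens are aligned to the fixed consensus by ordinary
  Procrustes analysis, so the reference shape space never moves.
- **Reference morphospace.** PCA of the covariance of aligned reference
  coordinates (n−1 denominator, deterministic axis signs). Fossils are
  *projected*, never refit: `s = E_kᵀ (x − x̄)`. Canonical variate analysis on
  the first 13 PCs maximizes between-guild over pooled within-guild variance
  (generalized eigenproblem `B a = λ W a`, canonical scores whitened so the
  pooled within-guild covariance is the identity).
- **Disparity through time.** Sum of per-axis variances on PC1–PC4 per time
  bin, bootstrapped (resampling with replacement at group size), with Welch
  t-tests between bootstrap distributions across sequential bins and
  Holm–Bonferroni correction. PERMANOVA (Euclidean pseudo-F, unrestricted
  label permutations, `p = (#{F* ≥ F} + 1)/(n_perm + 1)`) tests guild
  separation globally and pairwise. Convex-hull area/hypervolume measures
  morphospace occupation.
- **Trajectories.** Fossils are assigned to time bins (ages in ka BP;
  a coarse 16.5/14.2/13.5/0 scheme and a fine 1-ka scheme
  16.5/15.5/14.5/13.5/0). Divergence vectors run from the earliest
  (early-wetland) fossil centroid to each modern guild centroid; a guild is
  *recovered* in a bin when its centroid falls inside the bin's fossil
  convex hull (CV1–CV2 or PC1–PC2).
- **Synthetic radiations.** `study-mimic`, `early-burst`, `constant-rate` and
  `null-generalist` presets generate 45-point tooth configurations
  (7 fixed landmarks + 38 evenly spaced outline semilandmarks) for 18 guilds
  with graded specialization, staged emergence, persistent generalists and
  nuisance rotation/translation/scale.

## Worked example

```sh
paleomorph run --preset study-mimic --out run1 --seed 1
paleomorph report run1/manifest.json
```

prints (abridged):

```
Disparity (sum of variances, PC1-PC4):
  wetland        n= 107  0.000681  [0.000490, 0.000856]
  shallow-lake   n= 298  0.002262  [0.002030, 0.002473]
  deep-lake      n= 112  0.003815  [0.003237, 0.004314]
  modern         n= 310  0.004671  [0.004335, 0.004939]

Significant sequential disparity changes (Holm):
  wetland -> shallow-lake: p_holm=0
  ...

PERMANOVA across guilds: pseudo-F=203.524, R2=0.922, p=0.001

Guild recovery per time bin (CV1-CV2 hull):
  early-wetland   0 guilds:
  wetland         2 guilds: demersal-insectivore, generalist
  shallow-lake   14 guilds: algae-scraper, demersal-detritivore, ...
  deep-lake      17 guilds: ...
```

Reading it: the simulated fossil record starts morphologically narrow
(wetland disparity 0.0007 in squared shape units, bootstrap 95% interval in
brackets), expands sharply through the shallow-lake phase, and approaches the
modern radiation's disparity; the 18 modern guilds are strongly separated in
tooth shape (PERMANOVA p = 0.001, the smallest value attainable with 999
permutations); and the fossil morphospace progressively overlaps more guild
centroids, earliest for the generalist and the least specialized guilds.

The same stages are available piecemeal (`simulate`, `align`, `ordinate`,
`disparity`, `permanova`, `trajectories`), each consuming the previous
stage's CSV artifacts, and as library functions (`paleomorph.gpa`,
`fit_reference_pca`, `fit_cva`, `bootstrap_disparity`, `permanova`,
`guild_recovery`, ...). Runs are deterministic given the configured seed; the
JSON manifest records every parameter needed to reproduce a run bit-for-bit.

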