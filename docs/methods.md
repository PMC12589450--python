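# Methods

This note documents the statistical machinery, the conventions that make
results reproducible, the design of the synthetic radiation generator, and
the limits of what the validation suite demonstrates.

## Superimposition

Configurations are translated to the origin, scaled to unit centroid size
(`CS = sqrt(Σ‖xᵢ − x̄‖²)`) and rotated. Optimal rotations are solved by SVD
of the 2×2 cross-covariance with a determinant correction so that only
proper rotations are returned; teeth are photographed in a consistent
orientation, so reflections are treated as errors, never as fits.

Generalized Procrustes analysis iterates rotate-to-consensus /
recompute-consensus from the first specimen (centered and scaled) until the
unit-normalized consensus moves by less than `tol = 1e-8` in Frobenius norm
(typically 3–6 iterations at study scale; `max_iter = 100` with a warning
flag on non-convergence). The final configuration set is rotated so the
consensus's principal axis lies along x, with a 180° disambiguation by the
sign of the consensus's x-skewness; this makes aligned coordinates
insensitive to specimen input order to ~1e-8. The stored consensus is the
exact coordinate-wise mean of the aligned set.

Scaling is on by default even though size could be retained: tooth size
varies strongly with fish age, so raw-size superimposition would conflate
ontogeny with shape. `gpa(..., scale=False)` retains size for users who want
form-space analyses. No tangent-space projection is applied before PCA: at
the shape variation scales involved (Procrustes distances ≲ 0.2) the
orthogonal-projection correction is far below the sampling noise.

Fossils are never included in the GPA. They are aligned one at a time to the
fixed modern consensus by ordinary Procrustes analysis, which keeps the
reference morphospace stable as fossil material accumulates. Reference
specimens re-aligned this way reproduce their GPA coordinates to 1e-6.

## Ordination

The reference PCA eigendecomposes the covariance (n−1 denominator) of the
flattened aligned reference coordinates, centered on the consensus, so
reference scores have exactly zero column means. Axis signs follow a fixed
convention — the largest-magnitude loading of each axis is positive — so
orientations are identical across runs and platforms. Projection is the
linear map `s = E_kᵀ(x − x̄)`; model shapes along an axis are
`x̄ + s·e_axis`.

CVA is fit on the first 13 PC scores by default (configurable). It solves
`B a = λ W a` with `B` the between-group covariance (group-size weighted,
g−1 denominator) and `W` the pooled within-group covariance (n−g
denominator); eigenvectors are normalized so canonical scores have pooled
within-group covariance equal to the identity. The number of canonical axes
is `min(n_groups − 1, n_pcs_used)` — the rank of the problem; with 18 guilds
on 13 PCs that is 13, and 17 axes require at least 17 input dimensions. A
singular `W` falls back to pseudo-inverse whitening with a warning.

Whether the radiation's sister-species outgroup belongs in the PCA fit is
genuinely open; the package fits the reference space on the modern radiation
only and projects everything else, because projection keeps the reference
axes stable. Including extra specimens in the fit is a caller-side choice
(pass them to `fit_reference_pca`).

## Disparity and tests

Disparity is the sum of per-axis sample variances (n−1) of ordination
scores, on PC1–PC4 by default (4 axes). Each group is bootstrapped
(resampled with replacement at its own size, default `n_boot = 500`; 100 is
common in this workflow but noticeably noisy for downstream t-tests, and 500
keeps runtime trivial). Sequential comparisons are Welch t-tests between
bootstrap distributions — the convention of the disparity-through-time
workflow this mirrors — corrected with Holm–Bonferroni across the family
(adjacent bins in time by default; all pairs available). Note these t-tests
inherit the anti-conservativeness of treating bootstrap draws as samples:
with hundreds of draws, any real difference in point estimates is declared
significant. They rank and flag changes; they are not calibrated
hypothesis tests, which is why the tempo classifier (below) also uses
effect magnitudes.

PERMANOVA computes the pseudo-F from squared Euclidean distances using the
identity `SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g` (equivalent to
centered-coordinate ANOVA, no explicit centroids), with unrestricted label
permutations and `p = (#{F* ≥ F} + 1)/(n_perm + 1)`. The +1 correction keeps
p positive and gives the familiar floor of 0.001 at `n_perm = 999` (the
default). An exact mode enumerates all distinct labelings for small
problems. Pairwise PERMANOVA reports raw p always and Holm-adjusted p by
default, since whether such tables should be multiplicity-corrected is a
live methodological argument.

Morphospace occupation is the convex-hull area on the first two score axes
(matching the polygon convention of occupation plots) with an optional
4-axis hypervolume; degenerate point sets return 0 with a flag.

All stochastic operations take a seed and are independent of row order given
the seed: rows are put into a canonical order (by specimen id where
available) before resampling, and per-group/per-pair streams are derived
from the seed by fixed `SeedSequence` paths.

## Time bins and trajectories

Ages are in ka BP (larger = older). Coarse scheme: wetland 16.5–14.2,
shallow-lake 14.2–13.5, deep-lake 13.5–0. Fine scheme: early-wetland
16.5–15.5, wetland 15.5–14.5, shallow-lake 14.5–13.5, deep-lake 13.5–0, with
an additional late-Holocene slice (age ≤ 4.5). A shared bin edge belongs to
the *younger* bin (membership `younger < age ≤ older`; the youngest bin also
includes its own younger edge, so age 0 is binned). The "~" on real age
models makes any such rule a convention; it is recorded per run in the
manifest.

The ancestral centroid is the mean of the early-wetland (16.5–15.5 ka)
fossil scores, computed in the same space (CV or PC) as the guild centroids
it is compared against — centroid positions are projection-dependent, so
mixing spaces is not allowed. Divergence vectors are
`guild centroid − ancestral centroid` with Euclidean lengths; lengths are
invariant to rigid motions of the score space.

Recovery: a guild counts as recovered in a bin when its modern centroid lies
inside or on the convex hull of the bin's fossil scores (boundary-inclusive,
via the hull's facet equations with a 1e-9 relative tolerance; default
CV1–CV2, dims configurable). Hulls are sample-size sensitive — the coarse
bins range from n = 6 to n = 359 — so an alternative criterion (centroid
within the α-quantile Mahalanobis ellipse of the bin's scores, default
α = 0.95) is provided for small bins.

### Tempo classification

`classify_tempo` labels a fossil disparity trajectory over ordered time bins
as `early-burst`, `constant-rate` or `flat`. With no Holm-significant change
anywhere: `flat`. Otherwise the deciding signature is the fraction of final
fossil disparity already attained before the last bin, `D[-2]/D[-1]`: a
constant-rate radiation is still accumulating guilds in its last bin (small
attained fraction), an early burst is not. The label is `constant-rate` when
the final adjacent comparison is a significant *increase* and the attained
fraction is below 0.45, else `early-burst`. The threshold sits between the
simulated regimes' observed ranges (early-burst ≈ 0.54–0.78, constant-rate
≈ 0.23–0.38 at study-scale sample sizes). A pure
point-significance rule would not work here: the bootstrap t-tests flag any
real difference, and because specialists (large divergences, hence large
variance contributions) emerge last under the generalist-to-specialist
schedule, fossil disparity rises into the last bin under *every* tempo. The
modern reference bin is excluded from the rule because balanced modern
sampling inflates between-guild variance relative to abundance-weighted
fossil sampling regardless of tempo.

## Synthetic radiations

The generator produces the statistical structure the analysis assumes, with
planted parameters the pipeline should recover.

**Template.** A deterministic bicuspid crown: the graph of a two-Gaussian
height profile (major cusp at x = −0.30, height 1.0; minor cusp at x = 0.42,
height 0.62), guaranteeing a simple outline. Seven fixed landmarks (bases,
shoulders, two apices, inter-cusp notch) plus 38 semilandmarks evenly spaced
by arc length; centered, unit centroid size.

**Guild means.** Each guild's mean is `base + d_g · u_g` with `d_g` its
divergence (full Procrustes distance from the generalist, to first order)
and `u_g` a unit direction in a 4-dimensional subspace of smooth deformation
fields (low-frequency sinusoids of outline position, orthogonalized against
translation/scale/rotation). Directions carry 80% of squared magnitude in
the first two modes, angles advancing by the golden angle from a
seed-dependent offset, so guilds spread around the generalist center of the
leading morphospace plane. Directions are drawn once per seed and then
fixed: guild identity is a fixed effect, specimen noise a random effect.

**Defaults as study conditions.** 18 guilds; divergences graded 0 (the
generalist) through 0.035–0.10, increasing with emergence lateness
(increasing specialization); staged emergence: generalist at 16.5 ka, four
guilds at 15.4–14.7 ka, ten at 14.45–13.55 ka, three late specialists at
12/8/4 ka. Modern reference: 310 teeth spread evenly over guilds. Fossils:
fine-bin counts 6/40/359/112; shallow-lake ages are drawn so that exactly 61
fall in (14.2, 14.5] — the only age distribution under which the coarse
scheme simultaneously yields its design counts 107/298/112.
Fossil guild draws are multinomial over the guilds emerged at each
specimen's age, with the generalist weighted 5× (it persists in relative
abundance); every non-empty bin contains at least one generalist.

**Noise.** Isotropic Gaussian perturbation of every landmark coordinate,
default sd σ = 0.0044 shape units, chosen analytically so the reference
PCA concentrates ≈ 75% of total variance in PC1–PC4: with the between-guild
variance `B = Σ d_g²/18` confined to a 4-dimensional subspace and isotropic
noise spread over the ≈ 2p − 4 = 86 free shape dimensions, the PC1–PC4 share
is `(B + 4σ²)/(B + 86σ²)`, giving `σ² = (0.25/60.5)·B ≈ 1.94e−5` for the
default divergences. Isotropic noise was chosen over correlated deformation
noise for analyzability; a `smooth` noise mode (half the variance through
the deformation modes) is available because real tooth variation is
spatially correlated. One consequence of the isotropic default: per-axis
within-guild spread is tiny relative to between-guild spacing, so simulated
guilds are more cleanly separated in ordination space than real ones — the
PERMANOVA pseudo-F on simulated data (≈ 200) should be read as "guilds
separable", not as a realistic effect size.

**Nuisance.** Each specimen is randomly rotated (0–2π), scaled
(log-uniform 0.5–2× around a 100 px base) and translated (±100 px), so
superimposition genuinely has work to do; `within_sd = 0` with no nuisance
reproduces the mean exactly.

**What passing does not show.** The generator emulates the *statistical*
structure — guild geometry, abundance, staging, sample sizes — not
biomechanics, digitization error structure, age-model uncertainty, habitat
bias of deep coring sites, or missing/broken landmarks. Validation results
quantify what the pipeline can recover under its own assumptions; transfer
to real data depends on how far those assumptions hold.

## Validation experiments and problem sizes

`paleomorph.validation` runs the full chain per replicate (simulate → GPA →
PCA/CVA → coarse-bin disparity + tests → fine-bin recovery). The test suite
uses 50 replicates per preset for tempo classification and recovery timing
(study-scale sizes: 310 + 517 specimens per replicate), 200 null simulations
(n = 20, `n_perm = 199`) for permutation-test calibration, 25 datasets of
n = 200 for bootstrap calibration (a single n = 200 disparity estimate has
≈ 5% sampling sd, so the bootstrap mean is averaged over replicate
datasets), and 10⁶-sample brute-force oracles for rotation and hull-area
checks. The acceptance script uses 20 replicates per recovery/tempo
experiment; spot checks across seeds show the reported quantities stable to
well within their statistical noise. Emergence-order agreement is
summarized as the *median* per-replicate Spearman ρ between planted
emergence ages and first-recovery bins: recovery times take only four
discrete values, and tie-heavy replicates make the minimum an unstable
summary.

## Numerical conventions

- Covariances use n−1 throughout; eigenvalues are clipped at 0.
- Degenerate inputs fail loudly: coincident landmarks, zero-length curves,
  single-specimen variances, empty centroids and sub-simplex hulls raise
  typed errors or return flagged zero measures.
- Bootstrap/permutation streams derive from `SeedSequence([seed, index])`
  with fixed indices per stage/group/pair, so toggling one analysis never
  perturbs another's randomness and results are bit-reproducible.
- Tables are written with `%.12g` formatting; reruns with the same manifest
  are byte-identical (manifest timings excepted).
- TPS ingest applies `SCALE=` and flips y by default (image convention);
  the flip changes signs of shape axes only, never distances. Curves are
  resampled to evenly spaced semilandmarks once at ingest and treated as
  fixed landmarks afterwards — no semilandmark sliding; "evenly spaced" is
  taken literally. Missing landmarks are not supported.
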