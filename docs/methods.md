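# Methods

## Scope and data model

The package analyses brain-wide activity maps built from cFos-driven
labelling: a 3D intensity volume per channel (tdTomato for encoding-labelled
cells, cFos for recall activity, NeuN for total neurons,
autofluorescence for registration elsewhere), a pre-aligned integer label
volume with a region ontology, and tidy per-region count tables for three
behavioural cohorts — home cage (HC), contextual fear conditioning (CFC) and
recall (RE). Image registration, stitching and illumination correction are
upstream of this package: it consumes aligned volumes. Arrays are indexed
(x, y, z), 0-based, with physical coordinates `index × voxel_size` in µm.

## Detection pipeline

1. **Down-sampling** (optional): block-mean pooling in xy by an integer
   factor (e.g. 4× from a native 0.585 µm xy sampling to 2.34 µm); extents
   must be divisible, no padding.
2. **Candidate proposal**: the volume is Gaussian-smoothed with an
   isotropic-in-µm sigma (default 2 µm). Candidates are strict local maxima
   (26-neighbourhood; plateau components collapse to their lexicographically
   smallest voxel) above `intensity_floor × max(smoothed)` (default floor
   0.5). Peaks closer than `min_peak_separation` (default 8 µm) merge to the
   brighter peak, ties lexicographic. Surviving peaks seed a
   marker-controlled watershed on the inverted smoothed intensity restricted
   to the above-floor mask — one candidate per basin, at its seed.
3. **Curvature/intensity filter**: a central-difference Hessian of the
   smoothed volume (physical µm spacing) is evaluated at each candidate. A
   bright round cell has a negative-definite Hessian; the blobness score is
   the cube root of |λ₁λ₂λ₃| when all eigenvalues are negative, 0 otherwise.
   Candidates with zero blobness, blobness below `curvature_floor`
   (default 0 — only negative definiteness required) or peak intensity below
   the floor are rejected.
4. **Patch extraction**: 16 × 16 × 8-voxel patches centred on each
   candidate, min-max normalised to [0, 1] (constant patches map to zeros).
   Candidates within half a patch of a face are rejected (`rejected_border`)
   rather than zero-padded, so classifier inputs are homogeneous.
5. **Patch classification**: a logistic regression over 10 summary features
   of the normalised patch (centre and core intensity, global mean/sd,
   core-minus-shell contrast, Gaussian-template correlation, mean and max
   gradient magnitude, centre blobness, bright-voxel fraction), standardised,
   with a stratified held-out split reporting `holdout_accuracy_`. The
   classifier sits behind a fit/predict_proba interface so a 3D CNN can be
   substituted without touching the pipeline. Probability ≥
   `classifier_threshold` (default 0.5) accepts a candidate.

Every proposal ends in exactly one state (`accepted`, `rejected_filter`,
`rejected_border`, `rejected_classifier`); this partition is asserted in
tests across seeds.

## Region counting

Each accepted centroid takes the label at its own voxel (no neighbourhood
vote). Label 0 is outside the brain; regions flagged excluded in the
ontology (medulla — unreliable segmentation in cleared hemispheres; fiber
tracts — negligible activated-cell content) are dropped with the reason
recorded. Counts are zero-filled over all included regions, and the column
sum always equals the number of assigned, non-excluded centroids.
Fold-changes normalise CFC and RE cohort means by the HC mean; a zero HC
mean flags the region as undefined rather than dropping it. The hemisphere
is the counting unit; the packaged synthetic ontology defaults to 247
included regions.

## Engram-index statistic

Per region, a one-way ANOVA over the three cohorts followed by Tukey HSD
pairwise comparisons (raw counts, subject as replicate). A region is
*significant* when both CFC–HC and RE–HC are pairwise-significant at
α = 0.05 with positive differences. No cross-region multiplicity correction
is applied by default; Benjamini–Hochberg over each pairwise family is an
explicit opt-in, as is a log1p transform for heavy overdispersion. For
significant regions the engram index is
`log10(|μ̄_CFC − μ̄_HC| / |μ̄_CFC − μ̄_RE|)`; a zero numerator or denominator
leaves the index undefined — such regions are flagged and listed after the
ranked entries instead of being epsilon-padded, so printed rankings are
never artifacts of a smoothing constant. Ranking is by descending index,
ties broken by acronym.

The joint two-arm gate makes the empirical null pass rate far below α (both
one-sided wins must co-occur), which the type-I simulation confirms; it is a
screen rather than a calibrated test.

## Reactivation statistic

The cFos channel is smoothed and quantile-normalised (1st–99.9th percentile
→ [0, 1], clipped) into an intensity probability map; the construction is
monotone in intensity and pluggable so a learned foreground model can
substitute. A tdTomato centroid counts as reactivated when the map value at
its voxel is ≥ 0.6 (voxel membership, no dilation). Per region, the chance
level is `100 · n_cFos / n_NeuN` with counts pooled across subjects — the
probability that a randomly chosen neuron is recall-active — and
significance is a two-tailed one-sample t-test of per-subject percentages
against chance, requiring the mean to exceed chance. Zero variance across
subjects short-circuits (p = 1 at chance, otherwise flagged degenerate).
Cross-list consistency between the index ranking and the reactivation
ranking is |A ∩ B| / |A|.

## Manipulation-response statistics

Per-region cFos densities (cells/mm²) for control vs manipulation groups:
ratio of group means, unpaired two-tailed t-test (pooled variance),
tri-level call at α = 0.05. Heat-map export encodes signed significance
tiers (±1/2/3 at p < 0.05/0.01/0.001). Pattern similarity between
manipulation-driven and natural-recall ratios uses Pearson correlation with
a two-tailed p over regions shared by both contrasts (≥ 3 defined pairs
required). The engram-specific call set is the set of directional calls in
the engram contrast not reproduced by the random-labelling control
contrast.

## Synthetic-data generators

* **Volumes**: cells are isotropic-in-µm Gaussian blobs (σ = 3 µm, peak
  1000 AU) at integer voxel centres placed by rejection sampling at
  ≥ 12 µm separation and at least half a patch from every face, over
  N(300, 100) background noise clipped at zero — peak/noise-sd SNR 10.
  Optional distractor speckles (σ = 1 µm, peak 3000 AU) imitate staining
  noise bright enough to pass the intensity floor, giving the patch
  classifier real work. Placement failures raise, never silently fewer
  cells. Default frame 128 × 128 × 32 voxels at 1.8 × 1.8 × 2.0 µm.
* **Cohort counts**: negative-binomial (NB2: variance m + α·m², α = 0.1 by
  default, α = 0 exactly Poisson) around `baseline_mean × fold`, with
  class-typed regions — engram (CFC ×4, RE ×3.5), shock-only (×4, ×1),
  recall-preferential (×2, ×4), null (×1, ×1) — and cohort sizes 7/10/9
  (HC/CFC/RE). Baseline 100 cells/region is a free choice of a plausible
  magnitude; region-level baseline heterogeneity is not simulated.
* **Reactivation**: per subject and region, overlap ~
  Binomial(n_tdTomato, p) with fixed marginals and NeuN denominators for
  chance levels.

What the generators do **not** emulate: optical stripes and attenuation,
tile seams, registration error, anisotropic or touching cells, spatially
correlated background, inter-animal baseline variability and
region-size/count correlation. Passing benchmarks therefore demonstrate the
correctness and calibration of the algorithms under their stated noise
model, not detection accuracy on real cleared-tissue data, where the patch
classifier in particular would need retraining on annotated patches.

## Numerical choices and problem sizes

Ties at plateau maxima and equal-brightness peak merges resolve to the
lexicographically smallest voxel, making detection fully deterministic.
All generators and the classifier split are seeded; identical seeds give
bit-identical outputs. Test and acceptance runs use desk-scale problem
sizes — 50-cell volumes of 128 × 128 × 32 voxels, 1000-region null tables,
60-region class-structured tables, 1000-replicate calibration simulations —
chosen so the full suite completes in a couple of minutes while leaving
Monte-Carlo margins (3 SE, binomial 95% intervals) meaningful.

## Known limitations

The gate assumes approximately normal within-cohort counts at small n
(ANOVA on raw counts mirrors common practice; the log1p option exists for
heavy overdispersion). The engram index is undefined when encoding and
recall means coincide exactly and is noisy when they nearly do; it cannot
identify silent engrams (regions activated at encoding but not re-engaged
by natural recall). Chance levels pool counts across subjects; a
per-subject chance variant would propagate denominator uncertainty.
Detection assumes roughly spherical cells at a known scale and a single
global intensity floor per volume.
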