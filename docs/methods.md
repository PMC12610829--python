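# Methods

## Scope and data model

The unit of analysis is one bowel segment of one patient, described by
the raw MRE measurements the activity indices consume: wall thickness
(mm), the T2 signal-intensity ratio of the wall to the psoas muscle,
qualitative edema and ulceration flags, pre-/post-gadolinium wall
signal intensities with their image-noise SDs, an ordinal high-b DWI
signal score (0–3 by default), and the ADC in 10⁻³ mm²/s (typical
bowel-wall values 0.9–2.1; with this unit convention the ADC term of
DWI MaRIA is on the order of −1.3 to −2.8 index units, the only reading
that keeps the score on its conventional scale). Seven fixed anatomical
segments (I jejunum … VII sigmoid/rectum) cap the per-patient segment
count. Edema and ulceration arrive as precomputed binary flags; the
package does not re-derive them from signal. Only segments flagged
pathological enter the comparative analyses.

## Index formulas

RCE, MaRIA and DWI MaRIA are linear forms with fixed published
coefficients, collected in one `IndexCoefficients` object so a site can
recalibrate explicitly; there are no duplicated constants. A known
internal tension of the published group summaries is worth noting: the
per-group DWI MaRIA means printed alongside the per-group component
means are not reproducible from the DWI MaRIA formula under any
non-negative DWI score (e.g. 1.5·3.38 + 1.75·1.28 − 1.321·1.66 ≈ 5.1
against a printed group mean of 3.38). The formula is implemented
exactly as published; synthetic cohorts therefore reproduce the
formula-consistent values, not those printed group means.

## Gap clustering

Data-driven bands come from agglomerative single-linkage clustering of
one composite index at a time (1-D Euclidean distances,
z-standardization first, singletons to k = 3). Clustering on the
composite index rather than its components aligns the bands with how
cut-offs are used clinically. On the line the procedure has a closed
form — the k-cluster partition cuts the k − 1 largest adjacent gaps —
which the implementation exploits while still recording the full
agglomeration schedule (all n − 1 merges, heights non-decreasing) for
chaining inspection.

Numerical conventions:

* **Tie-break.** When several merges/cuts share a distance, cuts take
  the smallest left member index in sorted order; equivalently, tied
  merges are processed right-to-left. This makes results deterministic;
  it is checked for consistency between the agglomerative run and the
  closed form.
* **Duplicates** merge at height zero before any positive-height merge.
* **z-standardization** uses the sample SD (n − 1). The partition is
  invariant to this affine choice; schedule heights in z-units are not.
* **Cut-offs.** Each band's observed (min, max) in original index units
  is the cohort-specific threshold range; the midpoint of each
  inter-band gap is additionally reported as a single usable boundary.
* **Severity labels** attach to the three clusters by ascending cluster
  mean. k is configurable (default 3); for k ≠ 3 bands stay generic and
  the three-band marker convention and threshold comparison are skipped.

## Separation battery

Five analysis variables are fixed: T2 ratio, wall thickness, MaRIA,
DWI MaRIA, ADC. Per scheme the package computes:

* **Descriptives** per group and variable: mean, sample SD, min/max,
  CV = 100·SD/mean, 95% t-based CI of the mean
  (mean ± t₀.₉₇₅,ₙ₋₁·SD/√n), bias-corrected skewness G1 and excess
  kurtosis G2 (undefined below n = 3 / n = 4), Shapiro–Wilk normality
  p by default (the test behind published normality columns is rarely
  stated; it is configurable).
* **MANOVA**: Wilks' Λ = det(W)/det(W + B) with Rao's F approximation;
  for one variable this reduces exactly to the one-way ANOVA F (tested).
* **ANOVA and t-tests**: classical sums-of-squares F per variable;
  post hoc two-tailed pooled-variance t-tests (Welch behind a flag; no
  multiple-testing correction by default, a Bonferroni-style α
  adjustment can be emulated by passing a smaller α). Pairwise results
  are summarized by value order: the middle-valued group is starred *1
  when it differs from the lowest at p < 0.05, the extreme group *2
  when it differs from both others. The convention follows values, not
  severity, so for ADC the stars sit on the inactive group.
* **Discriminant contributions**: per-variable Fisher ratios
  (between-/within-group sum of squares on the given grouping)
  normalized to sum to 100%. The algorithm behind published
  "contribution %" columns is generally unstated; this normalization is
  a declared design choice, not a reconstruction.
* **Homogeneity**: resubstitution accuracy per group of a
  pooled-covariance, equal-prior linear discriminant classifier
  (ties to the lower group index). Resubstitution, not cross-validation,
  matches whole-group n/m accounting.
* **Mahalanobis distances** on the pooled within-group covariance
  S = W/(N − g), reported as D (a flag emits D²; published tables do
  not disambiguate the two).

Bands reduced to a single segment (possible under chaining-prone single
link) keep their descriptives and distances but degrade ANOVA cells to
NaN and carry no markers.

Reported tables round to 2 decimals, half away from zero; JSON output
keeps full precision.

## Synthetic cohorts

The generator emulates a three-archetype pathological cohort embedded
in a larger, mostly normal one (default pathological fraction 84/349).
Per archetype, (wall thickness, T2 ratio, ADC, RCE) are drawn from a
correlated multivariate normal — correlations default to +0.4
(wall–T2) and −0.4 (wall–ADC), an explicit assumption since group
summaries carry no correlations — truncated by resampling (not
clipping, to avoid point masses) to a physical lower bound of 0.1. The
DWI score is categorical per archetype; the post-contrast signal is
back-solved from the drawn RCE (baseline 100, equal pre/post noise SDs)
so the RCE formula returns the drawn value exactly.

The `maria_clusters` (n = 22/37/25) and `dwim_clusters` (n = 21/37/26)
presets carry the published per-group means/SDs of wall thickness, T2
ratio and ADC, and additionally accept a draw only when the computed
composite index falls inside that band's published (min, max) range.
The ranges matter: gap clustering only ever reports bands separated by
real gaps, so published per-band ranges are disjoint by construction,
and a faithful emulation must reproduce that gap structure — an
unconstrained Gaussian mixture with the same moments overlaps in the
lower components and chains under single link. RCE moments
(≈ 123/120/149 ± 60/40/75 %) and near-deterministic flag probabilities
(edema 0/1/1, ulceration 0/0/1) are back-derived from the published
MaRIA group moments via the MaRIA formula: interior Bernoulli flag
probabilities would add 5–10 index units of spread that the published
SDs (1.56–2.35) exclude. The generic archetype default keeps graded
flag probabilities for users building their own configurations.
`well_separated` (component gaps of tens of pooled SDs) and
`overlapping` (gaps under one pooled SD) are constructed extremes for
recovery and robustness testing.

What passing tests on these cohorts do **not** show: real cohorts need
not have clean inter-band gaps (the published ones did, by construction
of the clustering); real correlations, DWI-score codings and flag
prevalences are assumptions; and within-patient correlation beyond
shared patient ids is not modelled. Results on synthetic presets
demonstrate correctness of the machinery and qualitative behaviour,
not clinical performance.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through numpy
Generators. The bundled verification runs use cohorts of 349 segments
(84 pathological), 1,000 random instances (n ≤ 12) for the clustering
oracle equivalence, and 100 replicates for the threshold-vs-cluster
comparison — sizes at which every check completes in seconds while the
brute-force contiguous-partition oracle remains exhaustive. Pipeline
runs are byte-deterministic for a given (config, seed); manifests embed
config, package version and SHA-256 hashes of every output.

## Known limitations

* Single-linkage chaining is reported (schedule, dendrogram-ready) but
  not remediated; on overlap-heavy data the middle band can absorb most
  segments or shed singletons.
* Descriptive normality p-values and the contribution normalization are
  convention choices; published tables cannot pin them down.
* The criteria by which a segment is flagged pathological are upstream
  of this package; the flag is taken as input.
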