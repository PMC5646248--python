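# Methods

This note documents the statistical models, the numerical conventions, and
the deliberate design choices behind `starchlink`, in the order the
pipeline runs.

## Study design and data model

A crossover cohort assigns every subject one fecal sample per diet —
baseline washout, low resistant starch (LRS), and high resistant starch
(HRS) — coded as an approximate relative RS dose of 0, 0.05 and 1. All
stages operate on a `FeatureTable` (samples × features, one omics layer)
plus a sample-metadata table carrying subject, arm, diet, day and the coded
dose. Tables are stored features-in-rows on disk (the common omics
convention) and samples-in-rows in memory; the readers enforce the
orientation so no other code needs to care.

Zeros and missingness are distinct. In count layers (OTU, spectral counts)
a zero is an observation. In aligned metabolite matrices an absent peak is
conventionally stored as zero; the network stage recodes those zeros as
explicit missing markers before computing shared-sample statistics, and the
50 %-missing row filter counts only explicit markers.

## Per-layer preprocessing

**16S.** Samples are kept when their read total strictly exceeds 5,000;
OTUs are kept when they exceed a count of 5 in strictly more than 5 samples
(both thresholds configurable, and both readable as ≥ via a flag; the
strict reading follows the wording "more than"). Counts are then
proportionally scaled so every sample totals exactly 5,000 reads —
multiplication, not rarefaction, so within-sample proportions are preserved
exactly; a seeded rarefaction alternative exists but is not the default.
The prevalence filter reports the fraction of total observations retained.
Filters are idempotent and applied depth-first (removing shallow samples
changes prevalence, so the order is pinned and tested).

**Metaproteomics.** Spectral counts are normalized run-wise to the average
run total: each run's counts are multiplied by (mean run total)/(own run
total). After one pass all runs share the same total, the grand total is
conserved, and the operation is idempotent. The numerator of the printed
normalization ratio is read as the average run total — the only reading
under which the expression normalizes — and the worked two-run example in
the test suite pins it. Zero-count proteins are retained so downstream
joins stay aligned. Human and microbial proteins are normalized jointly by
default (separate by flag; the original processing order is not knowable).
Rollups to COG classes or taxonomic ranks pool unannotated proteins into an
explicit `unassigned` group so group totals conserve the matrix total.

**FT-ICR-MS.** Exported peak lists (m/z, intensity, optional S/N) are
filtered at S/N ≥ 4 (a peak *at* the export threshold is kept), then
aligned across samples at 1 ppm. The alignment dialect: pool all peaks,
sort by m/z, cut the sorted sequence wherever the gap between adjacent
peaks exceeds the tolerance relative to the gap midpoint, then verify every
member lies within tolerance of the group's intensity-weighted consensus
and split at the largest internal gap otherwise. This is deterministic and
independent of sample order; it is one of several valid alignment dialects
(a fixed-grid alternative would differ near bin edges). A sample
contributes at most one peak per group (closest to consensus wins); feature
IDs are the consensus m/z at 5 decimal places. The aligned matrix is then
filtered by occurrence (observed in ≥ 5 spectra) and mass defect
(fractional m/z ≤ 0.8); the two filters commute, so their order is
immaterial.

**Exact masses.** A single pinned table holds most-abundant-isotope masses
(C 12 exactly, H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117,
P 30.97376200 Da). Deprotonation subtracts the proton mass 1.007276 Da.
The AMP⁺ charge-tag arithmetic for derivatized carboxylic acids is
M − H₂O + C₁₂H₁₃N₂ using plain atomic sums for the cation, with no
electron-mass correction — the convention that reproduces the published
derivatized calibration masses to 4 decimal places (the electron-mass
variant would differ by ~0.0005 Da, visible at that precision). The test
suite cross-checks all mass arithmetic against an independent atomic-mass
table (pyteomics) to < 1e-4 Da. Short-chain fatty acids are quantified by
inverting an ordinary-least-squares external calibration line
(response = slope·concentration + intercept, 8 points typical).

## Dose-response statistics

The dose-correlation map computes, per feature and per subject, the Pearson
correlation of that subject's three diet samples against the coded doses
(0, 0.05, 1), then averages r across subjects. The per-subject reading —
rather than pooling all samples into one correlation — reflects the
within-subject crossover logic: every subject contributes one triple; a
pooled alternative is available by flag. Pearson's r makes the map
invariant to affine recoding of the doses. A subject whose abundance is
constant across diets has undefined r and is excluded from the mean;
mapping it to 0 instead would bias averaged maps toward null. Zero variance
is detected with a relative tolerance (1e-10 of the vector norm) so that
centering round-off cannot manufacture spurious correlations.

Diet comparisons use the Kruskal–Wallis test and the Nemenyi post-hoc test
on mean rank sums: pairwise differences of mean ranks are referred to the
studentized-range distribution (q = |R̄ᵢ − R̄ⱼ|·√2/SE with
SE = √(N(N+1)/12·(1/nᵢ + 1/nⱼ))); a tie-corrected chi-square variant
(statistic divided by 1 − ΣT/(N³−N), referred to χ²ₖ₋₁) is selectable.
Significance stars follow the 0.05/0.01/0.001 convention.

Heat-map preparation normalizes rows to (x − mean)/sd — sample (n−1)
standard deviation, a pinned convention since the cited clustering tool's
choice is unknowable — and clusters rows by Euclidean distance with average
linkage (the distance is prescribed, the linkage is not; average linkage is
the conservative default). Treemap tables aggregate mean abundance up a
feature hierarchy (weights) and carry abundance-weighted mean dose
correlations (colors); child weights sum to parent weights by construction.

## OPLS-DA

Two-class membership is coded as a single 0/1 response column, giving one
predictive component t[1] as in the standard presentation of two-class
OPLS-DA. The fit is the deterministic single-response O-PLS sequence: the
predictive weight vector w is obtained by NIPALS initialized from the
response (for a single response the loop converges immediately; tolerance
1e-10, cap 500 iterations); each orthogonal component is the part of the
X-loading orthogonal to w, removed from X by deflation before the final
predictive component is taken. There is no random initialization, so the
fit is reproducible bit for bit; the sign convention (second-listed class
has positive mean score) removes the remaining sign ambiguity. With zero
orthogonal components the model coincides with single-component PLS1-DA,
which the tests verify against an independently coded NIPALS oracle and
against scikit-learn's PLS implementation.

Unit-variance scaling (mean 0, sd 1 per feature, sample sd) is the default
everywhere — it is prescribed for the joint multi-omics matrix and adopted
as the default for single layers too, with `scaling="none"` available.
Zero-variance features are dropped with a warning rather than failing.

Q²(cum) = 1 − PRESS/SSY is computed by k-fold cross-validation (default 7),
with deterministic class-stratified folds: samples sorted by ID within each
class and dealt round-robin. When fewer samples than folds are supplied the
model fit falls back to leave-one-out; calling the CV routine directly with
folds > n is an error. `n_orthogonal="auto"` adds orthogonal components
while Q² improves by more than 0.01, a standard stopping rule (the original
component counts per model are unstated).

CV-ANOVA tests the cross-validated predictive residuals against the total
class variation: SS_total (DF = N−1) splits into SS_regression = SS_total −
PRESS (DF = A, the number of fitted components) and PRESS (DF = N−1−A);
F = MS_reg/MS_res is referred to F(A, N−1−A). A model with PRESS ≥
SS_total gets p = 1; a perfect cross-validated prediction reports p at the
machine floor with a warning. On 200 signal-free datasets (24 samples × 20
features, random labels) the empirical type-I rate at α = 0.05 sits inside
the binomial 95 % band around 0.05 (the test is conservative — under the
null PRESS usually exceeds SS_total — which is the known behaviour of
cross-validated ANOVA).

Significant features are selected per valid model (CV-ANOVA p < 0.05) by
the p-value of each feature's Pearson correlation with t[1] (< 0.05), then
unioned across models, each feature attributed to the class on whose side
of the predictive axis it loads. The exact S-plot/VIP thresholding of the
original software is unstated; VIP ≥ 1 is available as an alternative
criterion.

## CLR networks

Mutual information is estimated in bits by a plug-in estimator over
equal-frequency discretization: each feature's non-missing values are cut
at their own quantiles into B = ⌊√n⌋ bins (minimum 2), which makes the
estimate invariant under strictly monotone transformations and independent
of row order. Missing entries are pairwise-deleted; at least 8 shared
samples are required (a guardrail — MI at small n is fragile). The plug-in
estimator carries a positive bias of order (B−1)²/(2N ln2) bits under
independence; CLR is unaffected because its z-scores are background-
relative, and the tests assert estimator behaviour with that bias
accounted. The estimator is deliberately pluggable (the original CLR used
B-splines; the binning dialect is a documented choice).

CLR scoring: for each feature i, the background mean μᵢ and standard
deviation σᵢ of its off-diagonal MI row define zᵢ = max(0, (MIᵢⱼ − μᵢ)/σᵢ),
and the pair score is √(zᵢ² + zⱼ²) — the canonical rectified-z form. A
constant background row (σᵢ = 0) contributes 0 with a warning.

Network assembly follows the six-network merge rule: intra-layer edges come
from each single-layer table's own CLR network; inter-layer edges come from
the CLR network of the pairwise-combined, participant-matched table (match
key: subject × diet, the strictest consistent reading of participant
matching), taking only between-layer pairs. The 50 %-missing filter is
applied after matching, on the rows actually entering MI. Edges survive at
z ≥ 6.5 (inclusive; strictness is not stated, and the choice only matters
on a measure-zero boundary); nodes without surviving edges are dropped.
Node colors come from a two-sided two-sample t test (HRS vs baseline by
default): `higher`/`lower` at p < 0.05 by the sign of the mean difference,
else `neutral`; groups with fewer than 2 samples leave the node neutral
with a warning. Modules are connected components by default, or seeded
Louvain modularity maximization; modules are listed by size with ties
broken by smallest member ID, and hubs by degree with ties broken by node
ID.

## Synthetic cohorts

The generator emulates the crossover design: n subjects (default 23, the
low-carbohydrate arm size), three diets per subject, crossover diet order
alternating by subject, days 14/28/56. Count layers (OTU, spectral counts)
are negative-binomial with per-subject log-normal random intercepts
(subject sd 0.5 log units) — matching the overdispersion and the strong
interpersonal clustering of real cohorts — with per-sample depths drawn
log-normally (OTU: median 20,000, sd 0.3; spectral: median 6,000, sd 0.5,
deliberately unequal so the normalization stage has work to do;
dispersions 5 and 3). Metabolite intensities are log-normal (sd 0.4)
with missing-at-random zeros (default 20 %). All randomness flows from one
seed through a single generator object, so identical inputs give
bit-identical cohorts.

Planted effects act multiplicatively on the expected value (scale-free
across layers): `dose_linear` multiplies by exp(magnitude · dose), hence
monotone in the coded dose; `hrs_shift`/`lrs_shift` multiply by
exp(magnitude) in that diet only. Features sharing a `module_id`
additionally load on a common per-sample latent factor with loading equal
to the magnitude, creating cross-layer correlation. Effect magnitudes are
free parameters (the source study reports none): the defaults used in the
recovery experiments are 2.0 for single-feature effects and 4.0 for module
couplings — the latter sits at the plateau of the realized between-feature
correlation (~0.92–0.95 on the log scale): below it the coupling is weaker,
above it extreme latent draws saturate the compositional count layers and
correlation degrades again.

What the generator does *not* emulate: sequence-level reads, chimeras or
chimera filtering, profile-mode spectra, compositional interactions beyond
the shared total, batch effects, and clinical covariates. Passing recovery
tests therefore demonstrate statistical correctness of the pipeline on a
faithful abstraction of the data model, not performance on any real cohort.

A known limit worth stating: with 50 subjects (150 samples) and the
⌊√n⌋-bin estimator, the absolute CLR z of a maximally-coupled cross-layer
pair hovers near the 6.5 edge threshold — the inter-layer background noise
of the MI estimator bounds attainable z at this n, and z grows with sample
count. Planted-module recovery at the fixed threshold therefore yields
perfect edge precision and perfect module assignment but incomplete edge
recall; a threshold-free check (the strongest planted pair attains the
maximum inter-layer z in the network) is part of the test suite.

## Pipeline

`run_pipeline` drives data generation/loading, microbiome prep, proteomics
normalization, dose-response maps, the joint UV-scaled OPLS-DA and the CLR
network from one YAML mapping, writing stage-named subdirectories and a
manifest with the package version, the seed, the configuration, and sha256
checksums of every output. Re-running a configuration reproduces identical
outputs (asserted by test); stages recompute on every run — at the problem
sizes this package targets every stage completes in seconds, so checksum
verification replaced output caching as the reproducibility mechanism.
Layers absent from a configuration degrade gracefully: the network is
built from the remaining pair(s) with a logged warning.

## Problem sizes used in the validation suite

Recovery experiments run at 50 subjects × 3 samples with 60/50/70 features
per layer; null-calibration suites use 200 datasets of 24 × 20 (CV-ANOVA)
and 20 cohorts of 23 subjects with 40-feature layers (network
specificity); the end-to-end integration test runs at the 23-subject
study-arm scale. These sizes were chosen so the whole suite exercises every
statistical claim in well under a minute of compute per suite.
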