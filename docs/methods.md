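# Methods

## Problem

Ultra-rare syndromes often present a recognizable facial gestalt. When a
next-generation phenotyping system encodes face photographs as vectors in a
metric "phenotype space", the question *do the patients of this small cohort
resemble each other more than chance?* becomes a statistical one: compare the
cohort's internal distances with the distances seen (a) within established
syndrome cohorts and (b) across unrelated subjects drawn from a large
labelled gallery. `gestaltcohort` implements that analysis end to end,
together with the descriptive clinical tables (phenotype frequencies, ACMG
variant classification) that accompany such a cohort study.

## Embedding model and distance

Each image is represented by an ensemble of `E` unit vectors of dimension
`d` (defaults `E = 12`, `d = 512`), one per model / test-time augmentation.
Vectors are L2-normalized at load; normalization is a bitwise no-op on rows
that are already unit within 1e-12, so stored galleries round-trip exactly.
The distance between two vectors is the cosine distance `1 − ⟨u, v⟩ ∈ [0, 2]`.

The distance between two *images* averages member distances. By default
member `k` of image A is paired with member `k` of image B (one distance per
model/augmentation, `E` distances averaged); an `all_pairs` mode averaging
the full `E × E` grid is available via the `members` argument. Index
alignment is the default because ensemble members are produced by the same
ordered model stack for every image, so member `k` lives in the same
sub-space for both images; the all-pairs mean mixes sub-spaces and slightly
blurs contrast.

## Cohort-similarity analysis

Given a test cohort (subjects with one or more photos each) and a labelled
gallery:

1. **Test distribution** — resample, `n` times (default 100), one image per
   subject and record the mean pairwise distance of the sub-cohort. Sampling
   one image per subject prevents intra-subject similarity from inflating
   cohort similarity.
2. **"Same" null** — per draw, choose uniformly a gallery syndrome with at
   least two subjects, sample `min(size, available)` distinct subjects of it
   (one image each), record the mean pairwise distance. `size` defaults to
   the test cohort's subject count. Small syndromes contribute smaller
   sub-cohorts (minimum 2) rather than being excluded, mirroring the many
   small cohorts of real galleries; both choices are configurable.
3. **"Random" null** — as above but sampling subjects without any syndrome
   constraint.

Draws are independent across the `n` repetitions (identical sub-cohorts may
recur); within a draw subjects are distinct. Any test-cohort image present in
the gallery is removed before nulls are built (no leakage). Each stage uses
its own child generator spawned from the run seed, so stages are
independently reproducible.

## Threshold selection

A cutoff `c` classifies a sub-cohort as "same disorder" when its mean
pairwise distance is `≤ c` (inclusive, consistent with how sensitivity is
defined at the cutoff). Candidate cutoffs are midpoints between consecutive
distinct pooled sample values plus one sentinel below the minimum and one
above the maximum, which makes the inclusive rule unambiguous. Sensitivity is
the fraction of same-syndrome samples at or below `c`; specificity the
fraction of random samples above it. AUC is the Wilcoxon–Mann–Whitney rank
statistic (probability that a same-sample lies below a random-sample, ties
half-counted), which equals the trapezoidal area under the stepwise curve —
the test suite checks both routes agree to 1e-12 and cross-checks against
scikit-learn's `roc_auc_score`.

The operating point maximizes the Youden index `J = sensitivity +
specificity − 1`. The maximization uses the exact integer score
`m·TP + n·TN` rather than float `J`, so ties break deterministically toward
the smallest cutoff regardless of rounding. The deployable threshold is
fitted on all pooled samples; stratified k-fold cross-validation (default
`k = 5`) supplies out-of-fold sensitivity/specificity as a generalization
estimate. The fold unit is the resampled draw. Finally the fraction of the
test distribution at or below the fitted `c` summarizes how much of the
cohort's similarity mass lies in the "same disorder" regime.

## Rank analysis

For individual-level similarity, each cohort image in turn is the query; the
remaining cohort images are inserted into the gallery and the augmented pool
is sorted by ascending distance (ties broken by image id). The matrix of
1-based ranks the other cohort images attain is asymmetric in general, which
is expected and not corrected. Same-subject probe/query pairs are kept in the
pool but flagged, so summaries can exclude trivial self-similarity.

The top-k analysis (default `k = 30`) tallies the syndrome labels of each
cohort image's `k` nearest *gallery* images (cohort probes excluded from the
neighbourhood), sums tallies per subject, and reports each subject's modal
syndrome (ties broken lexicographically).

## Synthetic gallery generator

Real galleries are proprietary clinical photo collections, so validation
uses a generator with the hierarchy the analysis assumes: syndrome centres
uniform on the unit sphere; subject centres, image vectors and ensemble
members obtained by adding isotropic Gaussian noise (`sigma_subject`,
`sigma_image`, `sigma_ensemble`) to the parent vector and re-normalizing.
This perturb-then-normalize scheme is *not* exact von Mises–Fisher sampling
but has the same qualitative concentration geometry and needs no special
functions. Ids are systematic (`S001_P01_I01`), so syndrome/subject ground
truth is encoded in the id.

Defaults: 50 syndromes × 3 subjects × 2 images, `d = 512`, `E = 12`,
`sigma_subject = 0.2`, `sigma_image = 0.1`, `sigma_ensemble = 0.05`. The
subject and image spreads give clearly clustered but non-degenerate
syndromes (within-syndrome distances well below the between-syndrome level
of ≈1 for random directions); the ensemble spread is set below the image
spread, emulating mild test-time-augmentation jitter. A generated test
cohort defaults to four subjects contributing seven images in total (one to
three each), the shape of a typical ultra-rare case series. The
embedding-space experiments in the tests and the acceptance script run the
same gallery geometry at `d = 64`, `E = 3` so they complete in seconds; the
statistical structure is unchanged.

What the generator does **not** model: age/sex/ancestry covariates of facial
gestalt, heavy-tailed syndrome sizes, correlated (non-isotropic) embedding
noise, and any property of real photographs. Passing tests therefore show
the *pipeline* recovers planted structure under the stated geometry — they
do not certify performance on clinical galleries.

## Clinical tables

Phenotype frequencies use the floor-percent rule `floor(100·n/d)` with
patients lacking a recorded status excluded from the denominator — the rule
is inferred from, and checked against, the published aggregate column
(e.g. 5/12 → 41, 8/12 → 66, 7/11 → 63, 5/8 → 62). A two-class split printed
as complementary percents (5 F / 7 M → 41/59) gets the floor for the first
class and `100 − floor` for the second. The bundled per-patient matrix is a
synthetic reconstruction (only the two index patients' columns are published
per patient) constructed to reproduce every published aggregate count; the
published genitourinary row's n.a. count (1) is inconsistent with the cohort
size of 13, so the synthetic matrix uses 2 n.a. there — numerator,
denominator and percent are unaffected.

Variant carrier counts are distinct patients per cDNA change (homozygotes
once). The ACMG combiner implements the standard pathogenic-side combining
algorithm over {PVS1, PS1–4, PM1–6, PP1–5}; duplicates collapse, order is
irrelevant, and adding evidence never downgrades the class (property-tested).
PP5 is treated as an ordinary supporting criterion because the source
variant table uses it throughout. Two printed classifications
(`PP5+PM4+PM2 → Pathogenic`, `PM3+PM2+PP3 → Likely pathogenic`) do not
follow the standard algorithm (both are 2 PM + 1 PP → VUS); the combiner
keeps the standard rules and those rows are documented rather than
reconciled. Benign-side codes are out of scope.

## Determinism and numerics

Every stochastic stage takes a seed; the pipeline fans one global seed out
to per-stage child seeds by CRC-32 hashing of the stage name, so a stage
rerun alone reproduces its in-pipeline output. Reports are JSON with sorted
keys and no timestamps: same config + seed ⇒ byte-identical report. Distances
are clipped to [0, 2] against floating-point excursions and distance matrices
symmetrized by averaging. TSV vector I/O uses 17-significant-digit formatting
with round-trip float parsing, so text galleries are bit-exact.

## Known limitations

- The published operating point of the reference analysis (cutoff 0.909,
  sensitivity 0.862, specificity 0.792, 63.6% of the cohort distribution
  below the cutoff, best cross-subject rank 43) was computed on a
  proprietary gallery of clinical photographs and cannot be recomputed here;
  the synthetic analogue demonstrates the mechanism, not those numbers.
- The null-building sub-cohort size and the handling of small syndromes are
  assumptions (config-exposed) — the reference analysis does not state them.
- Nearest-neighbour search is exact and O(cohort × gallery); galleries far
  beyond ~10^5 images would want an ANN index, which is out of scope.
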