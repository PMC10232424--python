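# Methods

## Problem setting

Known pseudogene–miRNA associations define a sparse binary bipartite matrix
`PM` (at the reference data scale, 1570 positives among 318 × 260 = 82,680
pairs, leaving 81,110 unlabeled pairs). No confirmed negatives exist, so the
task is positive-unlabeled link prediction: score every unlabeled pair by
how likely it is to be a true association.

## Similarity kernels

Four pseudogene kernels and four miRNA kernels are computed. Two use side
information: Pearson correlation of expression profiles across conditions
(pseudogenes) and normalized target-set overlap
`|G_i ∩ G_j| / (√|G_i|·√|G_j|)` (miRNAs). Three use the interaction
profiles, i.e. rows/columns of `PM`: the Gaussian interaction profile
kernel with bandwidth `γ = 1 / mean squared profile norm`, Hamming profile
similarity (fraction of agreeing positions), and cosine similarity.

Conventions applied uniformly: outputs are symmetric with entries in [0, 1]
and unit diagonal. Negative Pearson correlations are clipped to 0 — the
fusion's normalization step requires nonnegative kernels, and clipping is
standard practice in similarity-fusion pipelines. Degenerate entities
(all-zero interaction profile, constant expression row, empty or missing
target set, or an entity absent from a side table) receive similarity 0 to
all others and self-similarity 1; this keeps every matrix a valid kernel
while carrying no spurious information, and it is how coverage gaps between
the three input tables are absorbed after identifier alignment. The Hamming
denominator is the profile *length* (not the number of ones); the
alternative reading would break the [0, 1] bound.

## Similarity kernel fusion

Each kernel is column-normalized into an initial status matrix
(all-zero columns become uniform so the operator stays stochastic for
isolated entities). A row-stochastic kNN sparsification of each *original*
kernel is the fixed local operator; neighborhoods `N_i` always include `i`
itself plus the `k−1` strongest neighbors, ties broken by ascending index
so runs are deterministic. The diffusion update replaces each status with
`α · F_r · (complement average of statuses) · F_rᵀ + (1−α) · (complement
average of initial statuses)`, followed by `(M + Mᵀ)/2` symmetrization
(the raw update does not preserve symmetry, and downstream feature rows
assume symmetric similarity). The complement average divides by `K−1`, the
number of other kernels — this is the only reading consistent with a
four-kernel stack and with the final `1/K` averaging; a
`legacy_denominator` flag reproduces the fixed `/2` variant that appears in
some write-ups of the method. Iteration stops after `n_iterations` or when
the largest entrywise change falls below `tol`; with `α ≤ 0.5` the update
is a contraction, so stopping at `tol` leaves at most `tol` of drift. The
final statuses are averaged and multiplied elementwise by the
mutual-neighbor weight matrix (1 if the pair are mutual kNN neighbors, 0 if
neither lists the other, 0.5 otherwise). The weight neighborhoods are taken
from the averaged kernel itself, with the same `k` and tie rule — the
per-kernel neighborhoods differ from each other, so a consensus definition
is needed, and the averaged kernel is the natural consensus.

Defaults: `alpha = 0.5`, `n_neighbors = max(3, round(0.3 n))`,
`n_iterations = 10`, `tol = 1e-6`. These follow common usage of
cross-kernel diffusion; none is critical, and all are exposed in
`FusionConfig` and as CLI flags.

## Ensemble and soft voting

A pair `(i, j)` is represented by concatenating row `i` of the fused
pseudogene similarity (length `n_p`) with row `j` of the fused miRNA
similarity (length `n_m`). Each of `n_learners` balanced subsets contains
every training positive plus an equal number of negatives drawn uniformly
without replacement from the unlabeled pairs; draws are independent across
subsets (subsets may share negatives — independence already makes them
distinct with overwhelming probability) and are derived deterministically
from a single seed. Within-subset sampling is without replacement so no
pair is duplicated. One gradient-boosted-tree classifier is fit per subset
(member seed = base seed + subset index); random forest, extremely
randomized trees and AdaBoost are available behind the same config for
ablation. Soft voting averages the member probabilities; a pair is called
associated iff the mean strictly exceeds 0.5. Defaults: 10 learners, 400
boosting rounds, learning rate 0.2 (the tuned gradient-boosting operating
point); remaining hyperparameters defer to the library defaults.

## Cross-validation protocol

Positives are partitioned into k seeded folds. Per fold, the test set is
the held-out positives plus an equal-sized sample of unlabeled pairs used
only for testing; training negatives are sampled from the unlabeled pairs
*excluding* those test negatives, and test-negative draws are per fold
(negatives are not reused across folds). In the default `masked` mode the
fold's training matrix has the test positives zeroed before the
GIP/Hamming/cosine kernels and the fusion are recomputed, so no held-out
association can influence any feature; the expression and target-set
kernels never touch `PM` and are computed once. A `full-matrix` mode
computes profile kernels from the complete matrix instead — this matches
the apparent protocol behind the very high AUCs published for methods of
this family, and is provided for comparability, but it leaks test edges
into the features and should not be used to claim performance.

With `training_fraction < 1`, a seeded subsample of the training positives
is used and the unused positives are also removed from the training matrix
and excluded from negative sampling — they are treated as genuinely
unknown, which is the cleanest emulation of "less training data".

The case-study ranker zeroes one pseudogene's entire row (only in `PM`;
side-information kernels are left intact, since expression and target data
would realistically still exist for an uncharacterized pseudogene),
retrains on everything else with that row excluded from negative sampling,
scores all miRNAs for the held-out pseudogene, and ranks them descending
with ties broken by ascending miRNA index.

Metrics: precision, sensitivity, accuracy, F1 and MCC from the strict >0.5
labels; AUC (trapezoidal, equal to pairwise concordance with half credit
for ties) and AUPR (trapezoidal area over the precision-recall points).
Ratios with zero denominators are reported as NaN, never silently 0.

## Synthetic data generator

The generator plants a stochastic block model: pseudogenes and miRNAs are
assigned uniformly to `n_blocks` latent blocks; `PM(i,j) = 1` with
probability `p_within` for same-block pairs and `p_between` otherwise;
expression row `i` is its block's mean vector (standard normal per
condition) plus i.i.d. noise of standard deviation `expr_noise_sd`; each
miRNA draws `targets_per_mirna` target genes, a `1 − gene_overlap` fraction
from its own block's pool of `genes_per_block` genes and the rest from the
other pools. All randomness derives from one integer seed, so a bundle is a
pure function of its arguments.

Defaults emulate the reference study conditions at reduced scale: 120 × 100
entities, 4 blocks, `p_within = 0.3`, `p_between = 0.02` (giving on the
order of a thousand positives at roughly the real data's ~2% density),
12 expression conditions (the order of distinct tissue/cancer contexts in
public pseudogene expression compendia), noise SD 0.5 (within-block
expression correlation ≈ 0.8, strong but not degenerate), and 20 targets
per miRNA with 10% cross-block leakage (realistic target-set sizes with
imperfect block separation). This produces data where every kernel carries
signal but none is perfect.

What the generator does *not* emulate: scale-free degree distributions,
correlated measurement noise across conditions, miRNA family structure,
identifier inconsistencies, or literature-driven ascertainment bias in
which associations get confirmed. Passing the synthetic benchmarks
therefore shows that the pipeline recovers plantable shared-neighbor
structure end-to-end under a leakage-safe protocol — not that any
particular AUC will transfer to real databases.

## Evaluation problem sizes

The shipped evaluation runs fivefold CV on the 120 × 100 bundle
(≈1100 positives) for the headline comparison, the training-fraction sweep
{0.25, 0.5, 0.75, 1.0}, and a shuffled-association null in which the same
number of positives is placed uniformly at random (side tables kept), which
should and does score near AUC 0.5. Functional and unit tests use smaller
bundles (30–60 pseudogenes) with reduced ensemble sizes; results there are
checked for properties (determinism, bounds, block recovery), not for
headline numbers.

## Known limitations

- Kernel weighting is uniform: fusion has no mechanism to down-weight an
  uninformative kernel beyond the diffusion's own averaging.
- Entities with no known associations and no side information are scored
  purely through the degenerate-kernel conventions and are effectively
  unrankable; the method cannot bootstrap a completely cold entity.
- Balanced subsets misstate the true class prior, so soft-vote scores are
  not calibrated probabilities; the 0.5 threshold is a convention, and
  threshold-free metrics (AUC/AUPR) are the primary measures.
- `functional_similarity` is quadratic in the number of miRNAs with Python
  set operations per pair; fine at the hundreds-of-entities scale this
  package targets.
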