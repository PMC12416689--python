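# Methods

## Model and procedure

`acgsfe` selects feature subsets for binary classification on
high-dimensional, low-sample-size expression data. The pipeline has a
fixed per-dataset stage and an iterated search stage.

**Per-dataset stage.** The data are split once into a stratified 80/20
train/test partition, with stratified 5-fold cross-validation folds
inside the training partition; one integer seed (default 42) drives both
through a dedicated RNG stream, so all search runs share identical
partitions. Features are then embedded as rows of the feature-by-feature
Pearson correlation matrix computed on the training partition only (no
test leakage): each feature's coordinate vector is its correlation
profile, so co-expressed features are close in Euclidean distance, which
is the metric Ward's minimum-variance criterion is defined for. The
number of clusters k is searched over [2, max], where
`divisor = 10·⌈ratio/100⌉` (minus 10 when the feature-to-observation
ratio is at least 300) and `max = ⌊ratio/divisor⌋`, clamped to at least
2 for small ratios. Each candidate cut is scored with the Davies-Bouldin
index (computed from the defining formula with direct Euclidean norms,
so it matches a textbook reimplementation to full float precision) and
the mean Silhouette (scikit-learn; singleton clusters contribute 0).
Uncomputable indices become NaN and exclude that k. Both score vectors
are min-max normalised over valid candidates and combined as
`0.5·norm(DB) + 0.5·(1 − norm(Sil))`; the k with the smallest combined
score wins, ties going to the smallest k (coarser grouping). If the two
normalisation extremes coincide the normalised value is defined as 0 for
all k (a constant term cannot discriminate). Constant features get
correlation 0 against all other features by convention, with the
diagonal kept at 1 so the embedding remains a valid correlation matrix.

**Search stage.** Each of `Run_max` independent runs starts from a
Bernoulli(0.5) mask (the uniform distribution over masks) and iterates
for `FEs_max` function evaluations:

1. Non-selection: clear `round(UR·D)` distinct selected bits, D the
   total feature count. UR follows the linear decay
   `UR(t) = (UR_max − UR_min)·(T − t)/T + UR_min`. The schedule is
   initialised once and evaluated at t−1 for iteration t, so the first
   iteration uses exactly UR_max and the rate decays toward UR_min. (A
   literal per-iteration reset to UR_max would pin the deselection count
   at its maximum forever, contradicting the decaying-rate design, so
   the reset is treated as one-time initialisation.) Rounding is
   half-away-from-zero; sampling is without replacement, since clearing
   the same bit twice is meaningless.
2. Selection (rescue): only if the mask emptied — restore the incumbent
   mask and switch `SN = 1` uniformly chosen non-selected bits on. This
   guarantees every fitness evaluation sees a non-empty mask.
3. Adaptive MI intra-cluster regularization: rebuild the candidate mask
   cluster by cluster, keeping the `min(limit, cluster candidates)`
   features with the highest mutual information with the label, with
   `limit = ⌈base·SF⌉`, `base = max(1, ⌈3·(T − t)/T⌉)` and
   `SF = 1 + (1 − t/T)·0.5·u`, one fresh uniform draw u per cluster in
   ascending label order. MI ties break to the lower feature index.
4. Fitness: mean over the 5 folds of 1-NN accuracy on the fold's
   validation part, features restricted to the candidate mask. The
   candidate replaces the incumbent iff fitness is **greater or equal**;
   tie acceptance matters, as it lets the search drift across accuracy
   plateaus toward the smaller, more stable subsets the late-stage cap
   produces.

After the budget, the best mask is evaluated once: a 1-NN fitted on the
full training partition predicts the hold-out. "Train accuracy" is
resubstitution accuracy of that model on the training partition (100%
for 1-NN unless duplicate points carry different labels), which makes
the train/test RMSE effectively the generalisation gap.

### Candidate scope of the regularization (a genuinely open choice)

The pruning step admits two readings of its candidate set, both
implemented behind `SearchConfig.regularize_scope`:

* `"all"` (default): every member of a cluster competes, so the output
  mask is rebuilt each iteration from the MI ranking and the stochastic
  cap alone, and the wrapper's accept/reject decision arbitrates between
  cap realisations.
* `"selected"`: only cluster members present in the incoming mask
  compete; the step strictly prunes the wrapper's proposal
  (output ⊆ input).

The default is `"all"`. With `"selected"`, masks quickly shrink below
the per-cluster cap, the pruning becomes a no-op for most iterations,
and the final subsets vary substantially across runs. Under `"all"`,
independent runs converge to near-identical subsets — mean pairwise
Jaccard similarity of 100% and zero standard deviation in subset size —
which is the run-to-run stability that characterises the method's
reported behaviour, and informative-feature recovery on synthetic data
is far stronger. `"selected"` remains available for studying the purely
wrapper-driven variant (`SearchConfig.sfe_baseline()` disables
clustering and regularization entirely, giving the plain SFE baseline).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fes_max` | 6000 | function evaluations (fitness calls) per run |
| `run_max` | 30 | independent runs per dataset |
| `ur_max`, `ur_min` | 0.3, 0.001 | non-selection rate endpoints (fraction of all features) |
| `sn` | 1 | bits re-selected by the rescue operator |
| `k_folds` | 5 | stratified CV folds for fitness |
| `knn_k` | 1 | neighbours of the KNN fitness classifier |
| `mi_bins` | 10 | equal-width histogram bins for MI (labels are never binned) |
| `split_seed` | 42 | seed of the shared train/test split and folds |
| `test_fraction` | 0.2 | hold-out fraction |
| `regularize_scope` | `"all"` | candidate set of the intra-cluster pruning |

MI uses natural logarithms; the base only rescales scores and the
pipeline consumes ranks. The bin count materially affects ranking noise
at small sample sizes and is therefore a config knob rather than a
constant. The positive class for the F-measure defaults to the minority
class (the protocol computes F-measures on imbalanced sets without
naming a positive class; the minority class is the informative choice).
The across-run standard deviation is the sample standard deviation
(n−1), as the runs are independent replicates. Jaccard stability is
aggregated over all unordered pairs of runs; "stable features" are those
selected in more than half the runs.

## Synthetic data generator

`SyntheticSpec`/`generate` emulate the statistical shape of microarray
benchmarks: features ≫ samples (the benchmark regimes span
feature-to-observation ratios of roughly 32–631 and imbalance ratios
1–4.84), block-correlated feature groups, and a small informative set.
Feature j in block b is `x_j = √ρ·f_b + √(1−ρ)·ε_j` with standard
Gaussian factors and noise, giving within-block correlation exactly ρ in
expectation and unit marginal variance; informative features get a
class-conditional mean shift of `effect_size` standard deviations and
are spread round-robin across blocks, mirroring the premise that
co-expression clusters contain few informative members. Labels are drawn
with exact class counts at the requested imbalance ratio. Defaults
(5 blocks, ρ = 0.5, effect 1.0, balanced classes, unit noise) were fixed
once as a mid-range regime of those shapes.

Not modelled: heteroscedastic and heavy-tailed array noise, batch
effects, probe-level artefacts. Passing tests therefore demonstrate
correct mechanics and recovery under idealised Gaussian block structure,
not performance on real arrays.

## Test and verification sizes

The test suite verifies closed-form quantities exactly (ratio, FRR, UR
schedule, cap formulas), checks the MI estimator and both cluster
validity indices against brute-force reimplementations (1e-12 and 1e-9),
and exercises the search invariants (non-empty masks over 10,000
operator applications, monotone fitness trajectories, bit-identical
reruns, per-cluster caps at every logged iteration). Recovery
experiments run at reduced scale chosen to keep the full suite fast:
cluster-count recovery on 500 features / 3 blocks / ρ = 0.9 / n = 100
over 10 generator seeds, and informative-feature recovery on a
60 × 500 fixture with 5 informative features at effect 2.0, 10 runs of
500 evaluations each. At those sizes a run takes a few seconds; the
qualitative behaviour (high FRR, stable subsets, regularized search
generalising at least as well as the plain baseline) matches the
full-scale configuration.

Degenerate inputs: constant features (zero MI, zero correlation), masks
emptied by the operators (rescued before evaluation), all-identical
embeddings (validity indices take the NaN pathway and k falls back to
the range minimum), and fully selected masks (rescue is a no-op) are all
defined behaviours with tests.

## Known limitations

* With `regularize_scope="all"` the non-selection/selection operators
  influence the outcome only through RNG stream consumption and the
  rescue path; the search is effectively over cap realisations. This is
  intrinsic to the literal pruning rule, and `"selected"` is provided
  for the alternative.
* MI histogram ranking is noisy below ~50 samples with 10 bins; on some
  data realisations a noise feature outranks a weakly informative one
  inside a large cluster, and the final subset then legitimately (by
  fitness) omits it.
* Only binary classification, 1-NN fitness and Ward/Pearson clustering
  are supported; multi-class labels, other classifiers and linkages are
  out of scope.
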