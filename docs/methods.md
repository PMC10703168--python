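# Methods

## The model

`microbiomegsm` classifies disease versus control from species-level
relative-abundance profiles by exploiting the taxonomy as prior knowledge,
in three stages (Grouping, Scoring, Modeling):

1. **Grouping (G).** Let `X` be the samples x species abundance matrix with
   binary labels (1 = disease), `S` its species set. At a chosen rank
   (genus, family, or order) the species are partitioned into groups
   `Grp{u} = {s in S : ancestor_rank(s) = u}` — e.g. all `Alistipes` species
   form one genus group. Grouping is purely taxonomic: it never sees samples
   or labels.
2. **Scoring (S).** On the training samples only, each group's sub-dataset
   `sub_d_u` (columns restricted to the group's species, labels kept) is
   scored by a random forest under stratified, shuffled 5-fold
   cross-validation; the group score is the mean fold accuracy. Groups are
   ranked by score, ties broken alphabetically, and the top k = 10 are kept.
3. **Modeling (M).** Cumulative models are fit on the training samples for
   m = 1..k: the model at depth m uses the union of the top-m groups'
   species (group-rank order, then within-group input order) and is
   evaluated on the held-out samples (accuracy, sensitivity, specificity,
   precision, F1, and rank-based AUC with ties counted 1/2).

The G-S-M loop runs inside Monte Carlo cross-validation: each iteration
draws a fresh stratified 80:20 train/test split and recomputes scoring and
ranking from that split's training half, so the ranking never touches test
data. Metrics are reported as means (and SDs) over iterations.

**Rank aggregation.** The per-iteration top-k lists are combined by robust
rank aggregation: an item at position j in a list over a universe of U items
gets normalized rank j/U (items absent from a list get 1.0). For an item's
sorted ranks r(1) <= ... <= r(N) across N lists, the beta score
`b_k = P(Bin(N, r(k)) >= k)` is the probability that the k-th order
statistic of N independent uniforms lies at or below r(k). Minimizing
`b_k` over k is a multiple test over N order statistics, so the item-level
score is Bonferroni-corrected by N — `rho = min(1, N * min_k b_k)`, the rank
aggregation method's significance bound (per rank vector this is
`rank_vector_p`; the uncorrected minimum is `rho_score`). `aggregate()` then
corrects across the universe of U competing items,
`p = min(1, rho * U)`, which is what the pipeline reports per group. With a
single list this makes every p equal 1 — single-run aggregation is
deliberately uninformative. Note the MCCV lists being aggregated share 80%
of their samples between iterations, so these p-values measure ranking
consistency across dependent resamples of one cohort, not independent
replication; the double correction keeps the null false-positive rate at or
below nominal in the calibration tests. Each species inherits its group's p-value
(`propagate`); aggregating the per-iteration species lists directly is
available as a variant (`direct`).

## Input handling

Merged abundance tables (clade strings x samples) are parsed as-is; only
rows whose deepest prefix is `s__` become features (strain `t__` rows and
higher-rank aggregates are dropped). Lineages with a missing intermediate
rank are gap-filled as `<deepest_known_ancestor>_unclassified`, so grouping
is always a total partition; such synthetic groups are ordinary groups,
mirroring the unclassified clades real profiles contain. Taxon names match
case-insensitively and are reported in their first-seen casing.

Each sample's species vector is closed to sum to 1. Closure is
scale-invariant, so percent-dialect and fraction-dialect tables normalize
identically and no magnitude-based dialect guessing is done. Samples without
a label or with any missing abundance cell are dropped (logged with counts);
an optional per-sample read-count table removes samples under 1,000,000
total reads (a no-op with a warning when no counts are supplied, since
merged tables do not carry them). Sample ids match by exact string after
whitespace stripping — silent fuzzy matches would be worse than an error.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `rank` | genus | grouping rank (genus, family, or order) |
| `k` | 10 | number of top-scoring groups carried into cumulative modeling |
| `n_folds` | 5 | internal CV folds for group scoring |
| `n_iterations` | 100 | MCCV repetitions |
| `train_fraction` | 0.8 | stratified train share per class (round half up) |
| `n_estimators` | 100 | trees per random forest (library defaults otherwise) |
| `decision_threshold` | 0.5 | probability cutoff for confusion-based metrics |
| `global_seed` | 0 | root of every derived seed |

Accuracy (not AUC) is the group score, and the random forest runs with
library-default hyperparameters — both deliberate, to keep the scoring rule
simple and reproducible. All randomness derives from the global seed via a
keyed hash `derive_seed(global_seed, iteration, tag...)`, so per-group and
per-iteration seeds are reproducible without being artificially correlated.

## Numerical and degenerate-input choices

- "Randomized stratified shuffling" for scoring is read as one seeded
  shuffle followed by a stratified k-fold partition; repeated stratified
  shuffle-split is available via `cv_scheme="shuffle_split"`.
- Group scores sort samples canonically (by sample id) before fold
  assignment, so scores are invariant to sample arrival order.
- If a group's minority class has fewer members than `n_folds`, the fold
  count drops to that size (minimum 2, logged); a single-class or
  minority-singleton sub-dataset is an error.
- Stratified split counts round half up per class on the train side, with
  at least one sample per class on each side.
- Undefined precision (no positive predictions) is reported as 0 with a
  `precision_defined=False` flag rather than NaN, so MCCV averages stay
  defined; F1 is 0 when precision + sensitivity is 0.
- Score ties in group ranking and p-value ties in aggregation break
  alphabetically (case-folded), making every output deterministic.
- The aggregation universe is the full group set at the chosen rank (a
  superset of items ever ranked), the conservative choice.

## The synthetic-data generator

The generator emulates the structure of species-level metagenomic cohorts:
30 genera nested three-per-family and three-families-per-order; 1–10 species
per genus; per-species baseline weights drawn log-normally (sigma = 1, a
heavy-tailed abundance spectrum); per-sample gamma noise with one unit of
concentration per species (a Dirichlet-like model); 200 samples, balanced
100/100 by default. Three informative genus groups have their species'
weights multiplied by `exp(effect)` (default effect 2.0, i.e. an e^2 ≈
7.4-fold relative shift) in disease samples, and closure is applied after
effect injection, so effects are relative exactly as in real compositional
data — null species are diluted by a common factor in the disease class, a
real compositional artifact the tests must (and do) account for.

What it does **not** emulate: taxon–taxon interactions, explicit
zero-inflation, sequencing-depth variation, batch effects, or the extreme
sparsity of real profiles. Passing the recovery and calibration tests
therefore shows the machinery is correct and well calibrated under a clean
compositional signal model, not that the method attains any particular
performance on real cohorts.

## Problem sizes used in tests and the acceptance script

The recovery and null-calibration experiments run 25 MCCV iterations at the
default cohort size (200 samples, 30 genera, k = 10); unit and property
tests use smaller cohorts (40–60 samples, 5–8 genera) and, where the check
is about bookkeeping rather than learning, 25–50 trees. The acceptance
script reruns both experiments end to end from the supplied seed.

## Known limitations

- Grouping ranks are restricted to genus/family/order; coarser ranks would
  be easy to enable but are untested.
- No hyperparameter tuning, nested CV, or probability calibration.
- Exact RRA p-value refinements (beyond the beta-score bound with Bonferroni
  correction) and alternative aggregation schemes are out of scope.
- With heavy class imbalance, accuracy-based group scoring favors
  majority-vote behavior; the score follows the method's definition rather
  than correcting for imbalance.
- When a large fraction of community weight shifts with the class, closure
  hands every non-shifted group a correlated dilution signal. Groups with
  few species whose shift is genuine then compete against many-species
  groups whose signal is pure dilution, and a single-species informative
  group can rank below them. The recovery tests expose exactly this regime:
  at a study seed whose informative draw is two large genera plus a
  singleton, the multi-species groups are recovered in every iteration at
  rho values near 1e-30 while the singleton never reaches the top k; at
  seeds where the total informative load is small (weak dilution), even a
  singleton informative genus is recovered consistently. This is a property
  of grouping compositional features, not of the implementation.
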