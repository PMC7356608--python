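# Methods

## Model and assumptions

`omcboost` fits per-case regression models of log10 IC50 drug response from a
single omics profile at a time. The core assumption is that for small
pharmacogenomics cases (45–62 cell lines, hundreds of features) predictive
signal, where it exists, is carried by a concise feature subset, and that the
number of useful features is itself a quantity to be estimated by
cross-validation rather than fixed a priori. The base learner is a
gradient-boosted regression-tree ensemble (XGBoost), chosen for its embedded
feature selection and tolerance of mixed binary/continuous inputs; the
complexity search complements it by shrinking the input space before the
learner ever sees it.

Responses are modeled on the log10 scale. Tables that report natural-log
IC50s must be converted explicitly with `natural_log_to_log10`
(multiplication by log10 e ≈ 0.4343); the converter is never applied
implicitly, so a mis-scaled response file fails loudly in validation rather
than silently shifting results.

## Stratification

Both evaluation sets are built on response ranks so they span the full
dynamic range:

- **Test split.** The global minimum and maximum responses always stay in
  training (trees cannot extrapolate beyond the training range). Ascending
  ranks 2 and m−1 are always held out; the remaining 8 of the 10 test ranks
  follow r_j = round(2 + j·(m−3)/9), j = 1..8, rounding half away from zero
  (platform-stable, unlike banker's rounding), with collisions advanced to
  the next unused interior rank. Ties in the response are broken by
  lexicographic cell identifier under a stable sort, so the split is a pure
  function of the data.
- **Folds.** The ranked training responses are cut into consecutive blocks
  of five; a seeded permutation scatters each block across the five folds
  (a partial final block goes to a random subset of distinct folds). This
  satisfies simultaneously: random assignment, fold sizes within one of each
  other (7–11 across n = 35–52), and every fold sampling every response
  stratum.

## Feature ranking

Univariate two-sided tests order features by association with the response:
Wilcoxon rank-sum (carriers vs non-carriers) for binary features, the
Spearman rank-correlation t-approximation for continuous ones. The Wilcoxon
p uses the exact null distribution whenever both groups have ≤ 25 members
and the pooled responses are tie-free, falling back to the normal
approximation with continuity correction otherwise — at fold-level group
sizes the exact path is the norm. P-values are an ordering device only; no
multiple-testing correction is applied because no significance claim is
made. Tie-breaking (common among binary features) is by descending absolute
effect — rank-biserial correlation for binary, Spearman rho for continuous —
then feature name, because the top-k subsets feed model training and must be
deterministic. Degenerate features (constant columns, one-sided carrier
groups) are kept with p = 1 rather than dropped, keeping feature indexing
stable across folds. Two-sided tests are used throughout: the direction of
sensitization is not presupposed.

## Complexity search

The candidate grid is every integer k in 2..⌊n/2⌋ (at least two training
instances per feature; floor for odd n). Within each fold the ranking is
computed once and reused for every k — for nested top-k subsets this is
mathematically identical to re-ranking per k and roughly 19× cheaper. A
complexity passes only if (a) the minimum validation-fold Spearman strictly
exceeds 0.25 — a profile at exactly 0.25 fails — and (b) no fold's model
predicts a constant (sample variance < 1e−8 on the log10 IC50 scale);
constant predictors carry no ranking information, and folds where the
correlation is undefined (constant predictions or constant observed
responses) likewise fail the profile. Among passing complexities the
highest median fold Spearman wins; median ties break toward the smaller k,
consistent with the goal of concise models.

## Final models and seeds

The final selected-k model and the all-features baseline are each 10-seed
ensembles (per-instance mean prediction; median available via
configuration), trained with the same conservative booster configuration:
learning rate 0.05, 700 trees, maximum depth 6, 0.8 row and column
subsampling per boosting iteration without replacement, all other learner
settings at the library defaults. No per-case hyperparameter search is
performed — with hundreds of cases it would be impractical and would invite
selection bias — and the same configuration serves both models so their
comparison isolates the feature selection. One master seed deterministically
spawns named sub-seeds (split, folds, per-fold boosters, final ensembles,
y-randomization) through `numpy.random.SeedSequence` spawn keys, so every
stage is independently reproducible and the whole per-case result document
is byte-identical across reruns.

Ensemble test performance is the Spearman correlation between the 10
mean-ensemble predictions and the 10 observed test responses
(mean-then-correlate); the per-seed-correlate-then-average variant can be
assembled from the per-model predictions but is not the shipped default.
R² is 1 − SS_res/SS_tot with SS_tot centered on the observed mean — the
definition under which negative values are possible and meaningful (a model
worse than predicting the mean).

## Validation machinery

Classification is two-gated: *not potentially predictive* when no complexity
passes the fold gate; *potentially predictive* when one does but test
Spearman ≤ 0.25; *predictive* when test Spearman > 0.25 as well.

y-randomization merges training and test rows (using every instance the
case has), restricts to the selected features, and runs 10 fresh
rank-stratified five-fold cross-validations with real labels and 10 with
freshly shuffled labels — both folds and booster seeds are re-drawn per run,
and shuffled-label stratification uses the shuffled values' ranks. Each
run's summary is the mean of its five validation-fold Spearman values, and a
two-sided paired t-test compares the two lists of 10. A caveat inherent to
this protocol: the 10 real-label runs share one dataset, so their values are
strongly correlated and the t-test's independence assumption is optimistic
on null data — the test is evidence against chance for strong signals, not
a calibrated per-case error rate.

The complementarity summary counts cases predictive by the selected-k model,
by the all-features baseline, by both, or by neither, reports the mean
paired test-Spearman difference with its paired t-test, and averages the
feature-reduction fraction 1 − k_opt/p over selected-k-predictive cases.

## Synthetic data

The generator emulates the data shapes the pipeline consumes: binary
features are i.i.d. Bernoulli (default mutation rate 0.1, in the range of
per-gene mutation frequencies in curated cancer-gene panels), continuous
features are i.i.d. standard Gaussian, and the response adds Gaussian noise
(in log10 IC50 units) to a planted signal from k_true features through a
linear, threshold (step at each feature's sample median — deliberately
tree-friendly, so purely linear signals do not under-test the learner), or
interaction link. Defaults mirror the eligibility floor: m = 45, hence
training n = 35 and k-grid 2..17; p defaults to 450 continuous / 470 binary
features, matching typical curated panels.

The reference panel used by the statistical acceptance checks is p = 200
continuous features with k_true = 5, effect sizes (1, 1, 0.8, 0.8, 0.6) and
noise SD 0.5 (signal-to-noise ≈ 14); null panels differ only in k_true = 0.
Features are i.i.d. — real omics matrices carry gene–gene correlation that
is deliberately not modeled — so passing tests demonstrate the machinery's
statistical behavior (error control, recovery, determinism), not performance
on biological covariance structure.

A note on what these conditions imply: with five features sharing a linear
signal, the strongest planted feature has population |rho| ≈ 0.51 against
the response, while the expected maximum null |rho| among 195 noise features
at the fold-ranking sample size (n = 28) is ≈ 0.54. Fold-level rankings
under the reference panel are therefore intrinsically noisy, and the
fraction of reference signal cases passing both gates settles near one half
— even an oracle handed the true five features clears the min-fold gate only
~90% of the time, since each of five validation folds has only ~7 points.
The false-positive side is unaffected (measured ≤ 1% on null panels); the
power side is a property of the panel, not of the implementation, and the
machinery tests use a deliberately stronger generator (p = 40, effects
(2, 2, 1.5, 1.5, 1.2), noise SD 0.3) where recovery is unambiguous.

## Numerical and engineering choices

- Spearman correlations use mid-ranks for ties; a constant vector raises a
  dedicated undefined-correlation error rather than returning a number.
- The test suite and worked examples use a 50-tree booster configuration for
  speed; the shipped default remains 700 trees. This is a configuration
  value, never a code path.
- Booster training is single-threaded and columns are addressed by feature
  name at prediction time, so results are invariant to feature column order
  and thread scheduling.
- Result documents serialize with sorted keys and NaN mapped to null; the
  run manifest (tool version, configuration hash, master seed, input paths,
  timestamp) is the only non-deterministic part.
- Matrix I/O is tab-separated UTF-8 with a required header row and a
  `cell_id` identifier column; rows of X and y align by identifier, never by
  file order.

## Limitations

- i.i.d. synthetic features understate the difficulty of correlated omics
  panels (and also understate the help correlation can give a ranking).
- The test-set size (10), fold count (5), and Spearman threshold (0.25) are
  protocol constants, exposed in configuration but not exercised at other
  values by the shipped tests.
- The y-randomization paired t-test is anti-conservative on null cases (see
  above); interpret small p-values on weak signals with care.
- Feature construction consumes pre-processed tables (variant lists, segment
  calls, normalized expression, averaged β-values); no variant calling,
  segmentation, or normalization is performed in-package.
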