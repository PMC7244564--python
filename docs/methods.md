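# Methods

## Problem and model

`bcpred` treats "is this protein related to breast cancer?" as supervised
binary classification on alignment-free sequence descriptors. The positive
class is a curated set of disease-essential proteins, the negative class a
set of non-cancer proteins; the fitted object is a pipeline (scaler →
feature selector → classifier) that maps any valid amino-acid sequence to a
probability of class membership. No structural, evolutionary or annotation
information enters the model: the assumption is that the compositional and
short-range-order signal in the primary sequence carries enough of the
class difference to rank candidates usefully.

## Descriptor families

All descriptors use the canonical alphabetical residue order
`ACDEFGHIKLMNPQRSTVWY`. AC, DC and TC are the overlapping k-mer frequency
vectors for k = 1, 2, 3 (denominators N, N−1, N−2) and each sums to 1.

APAAC and MB need per-residue physicochemical scales. Every 20-value scale
is standardized to zero mean and unit *sample* standard deviation (ddof = 1)
over the alphabet before use; the brute-force test oracles share this
convention, so it is load-bearing and must not be changed silently. APAAC
uses a hydrophobicity/hydrophilicity pair; MB uses eight AAindex-derived
scales (hydrophobicity, flexibility, polarizability, free energy of
solution, accessible surface area, residue volume, steric parameter,
relative mutability), shipped as versioned CSVs under `bcpred/data/` with
provenance in the file headers.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `apaac_lambda` | 30 | sequence-order tiers; APAAC emits 20 + 2λ = 80 features |
| `apaac_weight` | 0.05 | weight of the τ part in the joint normalization |
| `mb_nlag` | 30 | maximum autocorrelation lag; MB emits 8 × 30 = 240 features |

These are the conventional defaults of the R descriptor engines for these
families and are the unique values consistent with the family sizes 80 and
240. APAAC requires N > λ and MB requires N > nlag, so requesting either
family imposes a minimum sequence length of 31. The `Mix` concatenation has
20 + 400 + 8000 + 80 + 240 = 8740 columns; downstream zero-variance
filtering usually reduces this on real-sized datasets, and nothing in the
package assumes a particular post-filter count.

Note that APAAC's 2λ sequence-order components are weighted correlations,
not frequencies: the vector sums to 1 but individual τ components may be
negative. The normalization denominator 1 + wΣτ is guarded against
non-positivity (it can only fail for adversarial scales).

## Preprocessing

Order: duplicate-row removal → NA-row removal → zero-variance column
removal → min-max scaling to [0, 1] → SMOTE balancing. Scaling is fitted on
the training data only and applied with clipping to [0, 1], which keeps
chi-squared selection's non-negativity precondition satisfied on screening
data that falls outside the fitted range.

SMOTE is implemented directly (convex interpolation between a minority
point and one of its k = 5 minority nearest neighbours, u ~ U(0, 1)), with
a seeded generator; synthetic rows get identifiable `smote_*` ids. k = 5 is
the conventional default.

### Leakage

The classical workflow — and this package's default, for fidelity to it —
fits SMOTE and the feature selector on the **full** dataset before
cross-validation. This is optimistic: evaluation folds then contain
synthetic minority points interpolated from training minority points, and
the selector has seen the evaluation labels. The effect is not small. On
the synthetic null corpus (delta = 0, classes exchangeable by construction)
the default pipeline reports cross-validated AUROC near 0.99, while the
leakage-safe mode (`run_cv_leakage_safe`, CLI `--leakage-safe`), which
re-fits scaler, SMOTE and selector inside each training fold, reports ~0.5
as it must. Both figures are recomputed by `scripts/acceptance.py` so the
contrast is always visible. Any scientific claim of generalization
performance should be based on the leakage-safe mode; the default exists to
replicate the classical protocol.

## Feature reduction

Chi-squared k-best uses the feature-sum contingency statistic (observed =
per-class column sums, expected from class proportions), with ties broken
by column order so the top-k sets are nested in k. PCA keeps the k leading
components of the centred data; each component's sign is fixed by making
its largest-magnitude loading positive. The k grid {20, 100, 200, 300} is
capped at 300 because the modelled datasets have only a few hundred
instances.

## Benchmarking and model selection

The registry holds exactly 13 classifiers: NB, KNN, LDA, SVM-linear,
SVM-RBF, LR, MLP, DT, RF, XGB, GB, AdaB, Bagging. Hyperparameters are
library defaults except the MLP (one hidden layer of 20 units) and
stabilizers that do not change the model class (LR `max_iter=1000`,
single-threaded XGBoost for determinism). No hyperparameter search is done.
SVMs lack native probabilities; their decision function is passed through a
logistic squashing, which is monotone and therefore AUROC-preserving, but
uncalibrated — screening probabilities from SVM bundles are rankings, not
calibrated risks.

Cross-validation is stratified with shuffling under a fixed seed
(stratification guarantees both classes in every fold; fold SDs are
population SDs over the folds). Model selection is lexicographic: maximize
mean AUROC, then minimize AUROC SD, then minimize feature count. Bundles
persist the scaler and selector as JSON and the classifier via joblib;
loading a bundle reproduces the saving process's predictions bit-exactly.

## Screening and burden comparison

Screening featurizes with the bundle's own families and configuration,
drops (and logs) sequences below the descriptor minimum length, scales with
clipping, reduces, and sorts by predicted probability (stable sort, so
reruns are byte-identical). The decision threshold for the 0/1 label is
0.5.

The burden comparison is a two-sided Mann-Whitney U between the alteration
counts of predicted-positive and predicted-negative proteins: exact by full
enumeration of group assignments when both groups have ≤ 8 members (valid
under ties), tie-corrected normal approximation otherwise.

## Synthetic data generator

`generate_corpus` draws negative sequences i.i.d. from a uniform residue
distribution (1/20 each, chosen for analytic transparency; a natural-
frequency baseline can be supplied) and positive sequences from the mixture
(1 − δ)·baseline + δ·Uniform(S), with S = {K, R} by default. The signal
therefore lives at the composition (AC) level — so even 20-feature models
can detect it — and propagates into the k-mer and autocorrelation families.
Default study conditions: 140 positives vs 233 negatives, lengths uniform
on 50–500, δ = 0.05. The subset size |S| = 2 was fixed by a Mahalanobis
calculation: at δ = 0.05 and these lengths it puts the Bayes-level AUROC
near 0.96, i.e. strongly but not perfectly separable classes, the regime
the modelled problem lives in. δ = 0 makes the classes exchangeable and is
the null used throughout the tests.

What the generator does **not** emulate: real proteome length
distributions, domain structure, homology between the classes, or any
biological meaning of the shifted residues. Passing tests on this corpus
show the pipeline machinery is correct and that it detects compositional
signal at realistic effect sizes; they say nothing about how well real
disease proteins separate from non-cancer proteins.

`generate_burden` draws per-protein alteration counts as Poisson with base
mean 85 (the order of magnitude of non-cancer group means in tumour-cohort
alteration matrices), shifted additively by `effect` for predicted-positive
proteins; it exists to calibrate and power-check the Mann-Whitney step.

## Numerical choices and degenerate inputs

- Descriptor computations are exact integer counting plus float division;
  the oracle-equivalence tolerance of 1e-10 absorbs only summation-order
  effects.
- Non-standard residues (B, J, O, U, X, Z) are rejected by default
  (`strict`); `drop` and `strip` policies log every affected record.
  Sequences are upper-cased before validation.
- Constant columns are removed by `clean`; the scaler refuses them, and the
  chi-squared selector refuses negative values, so misordered pipelines
  fail loudly rather than silently.
- `pick_best` operates on a table sorted with stable sorts; all CSV outputs
  are byte-reproducible under fixed seeds.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full pipeline at the study
scale (373 proteins, 8740 Mix features, 300 selected, 3-fold CV) and the
benchmark grid at reduced scale (two descriptor sets, one k, three
classifiers); these sizes exercise every code path while keeping the whole
suite in the tens of seconds on one CPU.

## Known limitations

- The default workflow's optimism (see Leakage) is inherited deliberately;
  the leakage-safe numbers are the defensible ones.
- Reported probabilities are uncalibrated for margin classifiers.
- The descriptor set is sequence-only; no 3D, graph-topological or
  evolutionary features.
- SMOTE interpolation in very high-dimensional sparse spaces (TC, Mix)
  produces synthetic points that are easily distinguishable from real
  ones, which is precisely what inflates the leaky null.
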