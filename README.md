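# bcpred

Sequence-based prediction of breast-cancer-related proteins.

Deciding which proteins are worth pursuing as disease biomarkers or drug
targets is expensive to do experimentally. `bcpred` implements a QSAR-style
alternative: learn a binary classifier that separates proteins strongly
associated with breast-cancer pathogenesis from non-cancer proteins using
nothing but their amino-acid sequences, then screen large external protein
lists (immunotherapy targets, metastasis drivers, RNA-binding proteins, ...)
and rank candidates by predicted probability of being disease-related.

## The method

Each protein sequence *s* of length *N* is encoded by five descriptor
families:

- **AC** (20): residue fractions *f_u* = count(*u*)/*N*.
- **DC** (400): overlapping dipeptide fractions, denominator *N* − 1.
- **TC** (8000): overlapping tripeptide fractions, denominator *N* − 2.
- **APAAC** (80): amphiphilic pseudo-amino-acid composition. With
  standardized hydrophobicity/hydrophilicity scales *H₁*, *H₂*, the
  sequence-order factors are
  τ₂ⱼ₋₁ = (1/(N−j)) Σᵢ H₁(sᵢ)H₁(sᵢ₊ⱼ) and τ₂ⱼ likewise with H₂,
  j = 1..λ (λ = 30). The feature vector is
  [f_u, w·τⱼ] / (1 + w·Στ) with weight w = 0.05, so all 20 + 2λ
  components sum to 1.
- **MB** (240): normalized Moreau-Broto autocorrelation,
  AC_P(d) = (1/(N−d)) Σᵢ P′(sᵢ)P′(sᵢ₊d) for 8 standardized
  physicochemical scales P and lags d = 1..30.

**Mix** is the concatenation of all five (8740 columns). The modelling
pipeline is: deduplicate sequences → assemble the labeled dataset →
remove duplicate/NA rows and zero-variance columns → min-max scale to
[0, 1] → balance the classes with SMOTE → reduce features (chi-squared
top-*k* selection or PCA, *k* ∈ {20, 100, 200, 300}) → benchmark 13
classifiers (NB, KNN, LDA, SVM-linear, SVM-RBF, LR, MLP, DT, RF, XGB, GB,
AdaB, Bagging) by stratified 3-fold cross-validated AUROC → pick the best
model (max mean AUROC, then min SD, then fewest features) → persist
scaler + selector + classifier as a reusable bundle. Screening applies a
saved bundle to new FASTA and a Mann-Whitney U test compares genomic
alteration burden between the predicted groups.

A caveat this package makes explicit: fitting SMOTE and the feature
selector on the *full* dataset before cross-validation (the classical
workflow, and the default here) is optimistic, because evaluation folds
contain synthetic points interpolated from training data. The
`--leakage-safe` flag re-fits scaler, SMOTE and selector inside each
training fold; use it whenever you care about unbiased performance
estimates rather than replicating the classical protocol.

## Worked example

Everything is available both as a library and through the `bcpred` CLI.
Generate a synthetic two-class corpus (140 vs 233 proteins, a delta = 0.05
compositional shift on K/R in the positive class), train the headline
configuration, and screen:

```bash
bcpred simulate --n-pos 140 --n-neg 233 --delta 0.05 --seed 11 --out-dir .
bcpred train-best pos.fa neg.fa --families Mix --reduction kbest-chi2 \
       --k 300 --classifier MLP --seed 11 --bundle-dir bundle
bcpred screen bundle pos.fa --tag demo --out preds.csv
```

which prints

```
wrote 140 positive and 233 negative records to .
MLP Mix/kbest-chi2-300: AUROC 0.995 +/- 0.0027, ACC 0.972 +/- 0.0120 (3-fold CV); bundle saved to bundle
screened 140 proteins; 137 predicted positive; wrote preds.csv
```

The AUROC line is the 3-fold cross-validated mean ± SD of the multilayer
perceptron (one hidden layer, 20 units) on the 300 chi-squared-selected Mix
descriptors; `preds.csv` lists the screened proteins sorted by predicted
positive-class probability. The same steps in Python:

```python
from bcpred import FixtureConfig, generate_corpus, train_model, screen

pos, neg = generate_corpus(FixtureConfig(delta=0.05, seed=11))
bundle, cv = train_model(pos, neg, reduction="kbest-chi2", k=300,
                         classifier="MLP", seed=11)
ranked = screen(bundle, pos + neg)
```

`bcpred bench` sweeps the full descriptor-set × reduction × k × classifier
grid and writes a benchmark table sorted by mean AUROC.

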