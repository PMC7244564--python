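"""Benchmark harness: 13 classifiers, cross-validated AUROC, model bundles.

The classifier roster is fixed at 13 named methods:

    NB, KNN, LDA, SVM-linear, SVM-RBF, LR, MLP, DT, RF, XGB, GB, AdaB, Bagging

Hyperparameters are library defaults except the MLP, which uses a single
hidden layer of 20 units. No hyperparameter search is performed. SVMs do not
emit calibrated probabilities; their decision function is mapped through a
logistic squashing, which preserves the ranking (all AUROC needs) without
claiming calibration.

Model selection is lexicographic: maximize mean AUROC, tie-break on smaller
AUROC SD, then on fewer features.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import selection
from .descriptors import DescriptorConfig, featurize, normalize_families
from .prep import (
    LabeledDataset,
    ScalerState,
    apply_scaler,
    clean,
    fit_scaler,
    smote_balance,
)
from .selection import SelectorState, fit_selector, transform
from .sequence_io import ProteinRecord

CLASSIFIER_NAMES = (
    "NB", "KNN", "LDA", "SVM-linear", "SVM-RBF", "LR",
    "MLP", "DT", "RF", "XGB", "GB", "AdaB", "Bagging",
)


class DecisionFunctionProba(BaseEstimator, ClassifierMixin):
    """Wrap a margin classifier, exposing predict_proba via a logistic map.

    expit is monotone in the decision function, so AUROC is unchanged;
    the probabilities are uncalibrated by construction.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator_ = clone(self.estimator).fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        p = expit(self.estimator_.decision_function(X))
        return np.column_stack([1.0 - p, p])


@dataclass(frozen=True)
class ClassifierSpec:
    """A named registry entry with optional hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def build_classifier(spec: ClassifierSpec):
    """Instantiate the classifier for a registry name, seeded from the spec."""
    name, seed, params = spec.name, spec.seed, dict(spec.params)
    builders = {
        "NB": lambda: GaussianNB(**params),
        "KNN": lambda: KNeighborsClassifier(**params),
        "LDA": lambda: LinearDiscriminantAnalysis(**params),
        "SVM-linear": lambda: DecisionFunctionProba(
            SVC(kernel="linear", random_state=seed, **params)
        ),
        "SVM-RBF": lambda: DecisionFunctionProba(
            SVC(kernel="rbf", random_state=seed, **params)
        ),
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed, **params),
        "MLP": lambda: MLPClassifier(
            hidden_layer_sizes=(20,), random_state=seed, **params
        ),
        "DT": lambda: DecisionTreeClassifier(random_state=seed, **params),
        "RF": lambda: RandomForestClassifier(random_state=seed, **params),
        "XGB": lambda: XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **params
        ),
        "GB": lambda: GradientBoostingClassifier(random_state=seed, **params),
        "AdaB": lambda: AdaBoostClassifier(random_state=seed, **params),
        "Bagging": lambda: BaggingClassifier(random_state=seed, **params),
    }
    if name not in builders:
        raise ValueError(
            f"unknown classifier {name!r}; valid names: {list(CLASSIFIER_NAMES)}"
        )
    return builders[name]()


def registry(seed: int = 0) -> List[ClassifierSpec]:
    """The full 13-entry roster, all seeded identically."""
    return [ClassifierSpec(name, seed=seed) for name in CLASSIFIER_NAMES]


def positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score used for AUROC and screening."""
    proba = model.predict_proba(X)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, pos_col]


def run_cv(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    n_folds: int = 3,
    seed: int = 0,
) -> Tuple[float, float, float, float]:
    """Stratified k-fold CV on a prepared dataset.

    Returns (mean AUROC, SD AUROC, mean accuracy, SD accuracy) over the
    folds (population SD). The dataset must already be cleaned, scaled,
    balanced and reduced — the default, leaky workflow.
    """
    X = ds.features.to_numpy(dtype=float)
    y = ds.labels.to_numpy()
    aurocs, accs = _cv_scores(X, y, spec, n_folds, seed)
    return (
        float(np.mean(aurocs)), float(np.std(aurocs)),
        float(np.mean(accs)), float(np.std(accs)),
    )


def _cv_scores(X, y, spec, n_folds, seed, fit_transform_per_fold=None):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aurocs, accs = [], []
    for train_idx, test_idx in skf.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError("a CV fold contains a single class")
        if fit_transform_per_fold is not None:
            X_tr, y_tr, X_te = fit_transform_per_fold(X_tr, y_tr, X_te)
        model = build_classifier(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_tr, y_tr)
            score = positive_proba(model, X_te)
            pred = model.predict(X_te)
        aurocs.append(roc_auc_score(y_te, score))
        accs.append(accuracy_score(y_te, pred))
    return np.asarray(aurocs), np.asarray(accs)


def run_cv_leakage_safe(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    reduction: str = "none",
    k: int = 0,
    n_folds: int = 3,
    seed: int = 0,
    smote_k: int = 5,
) -> Tuple[float, float, float, float]:
    """CV that re-fits scaler, SMOTE and selector inside each training fold.

    ``ds`` should be the *cleaned but unscaled, unbalanced, unreduced*
    dataset; every preprocessing step only ever sees training rows.
    """
    X_all = ds.features
    y_all = ds.labels.to_numpy()

    def per_fold(X_tr, y_tr, X_te):
        tr = LabeledDataset(
            pd.DataFrame(X_tr, columns=X_all.columns), pd.Series(y_tr)
        )
        tr, _ = clean(tr)
        scaler = fit_scaler(tr)
        tr = LabeledDataset(apply_scaler(scaler, tr.features), tr.labels)
        tr = smote_balance(tr, k_neighbors=smote_k, seed=seed)
        sel = fit_selector(tr, reduction, k, seed)
        tr_X = transform(sel, tr.features)
        te = apply_scaler(scaler, pd.DataFrame(X_te, columns=X_all.columns))
        te_X = transform(sel, te)
        return tr_X.to_numpy(float), tr.labels.to_numpy(), te_X.to_numpy(float)

    aurocs, accs = _cv_scores(
        X_all.to_numpy(float), y_all, spec, n_folds, seed, fit_transform_per_fold=per_fold
    )
    return (
        float(np.mean(aurocs)), float(np.std(aurocs)),
        float(np.mean(accs)), float(np.std(accs)),
    )


DEFAULT_FAMILY_SETS: Dict[str, Tuple[str, ...]] = {
    "AC": ("AC",),
    "DC": ("DC",),
    "TC": ("TC",),
    "APAAC": ("APAAC",),
    "MB": ("MB",),
    "Mix": ("AC", "DC", "TC", "APAAC", "MB"),
}

#: the k sweep used for both chi2 selection and PCA, capped at 300
#: because of the small number of instances.
DEFAULT_K_GRID = (20, 100, 200, 300)

BENCH_COLUMNS = [
    "descriptor_set", "reduction", "k", "classifier", "n_features",
    "auroc_mean", "auroc_sd", "acc_mean", "acc_sd", "n_folds", "seed", "error",
]


def prepare_dataset(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    families: Iterable[str],
    config: Optional[DescriptorConfig] = None,
    seed: int = 0,
    smote_k: int = 5,
    balance: bool = True,
) -> Tuple[LabeledDataset, ScalerState, dict]:
    """Featurize both classes and run the default preprocessing chain.

    Returns the scaled (and, if ``balance``, SMOTE-balanced) dataset, the
    fitted scaler, and the clean-report.
    """
    config = config or DescriptorConfig()
    fams = normalize_families(families)
    pos = featurize(pos_records, fams, config)
    neg = featurize(neg_records, fams, config)
    from .prep import assemble

    ds = assemble(pos, neg)
    ds, report = clean(ds)
    scaler = fit_scaler(ds)
    ds = LabeledDataset(apply_scaler(scaler, ds.features), ds.labels)
    if balance:
        ds = smote_balance(ds, k_neighbors=smote_k, seed=seed)
    return ds, scaler, report


def run_grid(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    family_sets: Optional[Dict[str, Tuple[str, ...]]] = None,
    reductions: Sequence[str] = ("none", "kbest-chi2", "pca"),
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    classifiers: Optional[Sequence[ClassifierSpec]] = None,
    n_folds: int = 3,
    seed: int = 0,
    config: Optional[DescriptorConfig] = None,
    leakage_safe: bool = False,
) -> pd.DataFrame:
    """Sweep descriptor sets x reductions x k x classifiers with k-fold CV.

    Returns a benchmark table sorted by mean AUROC descending. A failing
    combination is annotated in its ``error`` column rather than aborting
    the sweep.
    """
    family_sets = family_sets or DEFAULT_FAMILY_SETS
    classifiers = list(classifiers) if classifiers is not None else registry(seed)
    config = config or DescriptorConfig()
    rows = []
    for set_name, fams in family_sets.items():
        ds_prep, _, _ = prepare_dataset(
            pos_records, neg_records, fams, config, seed=seed
        )
        if leakage_safe:
            pos_m = featurize(pos_records, fams, config)
            neg_m = featurize(neg_records, fams, config)
            from .prep import assemble

            ds_raw, _ = clean(assemble(pos_m, neg_m))
        for reduction in reductions:
            ks = [0] if reduction == "none" else list(k_grid)
            for k in ks:
                if reduction != "none" and k > ds_prep.features.shape[1]:
                    continue
                if reduction == "pca" and k > min(ds_prep.features.shape):
                    continue
                if reduction == "none":
                    reduced, n_feat = ds_prep, ds_prep.features.shape[1]
                else:
                    sel = fit_selector(ds_prep, reduction, k, seed)
                    reduced = LabeledDataset(
                        transform(sel, ds_prep.features), ds_prep.labels
                    )
                    n_feat = k
                for spec in classifiers:
                    row = {
                        "descriptor_set": set_name, "reduction": reduction,
                        "k": k, "classifier": spec.name, "n_features": n_feat,
                        "n_folds": n_folds, "seed": seed, "error": "",
                    }
                    try:
                        if leakage_safe:
                            stats = run_cv_leakage_safe(
                                ds_raw, spec, reduction, k, n_folds, seed
                            )
                        else:
                            stats = run_cv(reduced, spec, n_folds, seed)
                        row.update(
                            auroc_mean=stats[0], auroc_sd=stats[1],
                            acc_mean=stats[2], acc_sd=stats[3],
                        )
                    except Exception as exc:
                        row.update(
                            auroc_mean=np.nan, auroc_sd=np.nan,
                            acc_mean=np.nan, acc_sd=np.nan, error=str(exc),
                        )
                    rows.append(row)
    table = pd.DataFrame(rows, columns=BENCH_COLUMNS)
    table = table.sort_values(
        "auroc_mean", ascending=False, kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table


def pick_best(table: pd.DataFrame) -> Tuple[pd.Series, str]:
    """Lexicographic best row: max mean AUROC, min AUROC SD, min features."""
    if table.empty:
        raise ValueError("benchmark table is empty")
    valid = table[table["auroc_mean"].notna()]
    if valid.empty:
        raise ValueError("benchmark table has no successful rows")
    ordered = valid.sort_values(
        ["auroc_mean", "auroc_sd", "n_features"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.iloc[0]
    rationale = (
        f"best of {len(valid)} rows: {best['descriptor_set']}/"
        f"{best['reduction']}/k={best['k']}/{best['classifier']} with "
        f"mean AUROC {best['auroc_mean']:.4f} (SD {best['auroc_sd']:.4f}, "
        f"{best['n_features']} features); criteria: max mean AUROC, "
        f"then min SD, then min feature count"
    )
    return best, rationale


# ---------------------------------------------------------------------------
# model bundle persistence


@dataclass
class ModelBundle:
    """Everything needed to score new proteins: scaler + selector + model."""

    scaler: ScalerState
    selector: SelectorState
    model: object
    config: DescriptorConfig
    families: Tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for a raw (unscaled) feature matrix."""
        scaled = apply_scaler(self.scaler, matrix)
        reduced = transform(self.selector, scaled)
        return positive_proba(self.model, reduced.to_numpy(dtype=float))


_BUNDLE_FILES = ("scaler.json", "selector.json", "model.joblib", "config.json", "metadata.json")


def save_bundle(bundle: ModelBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "scaler.json").write_text(bundle.scaler.to_json())
    (directory / "selector.json").write_text(bundle.selector.to_json())
    joblib.dump(bundle.model, directory / "model.joblib")
    (directory / "config.json").write_text(bundle.config.to_json())
    meta = dict(bundle.metadata)
    meta["families"] = list(bundle.families)
    meta.setdefault("created", time.strftime("%Y-%m-%dT%H:%M:%S"))
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1, default=str))
    return directory


def load_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    for fname in _BUNDLE_FILES:
        if not (directory / fname).exists():
            raise FileNotFoundError(f"bundle at {directory} is missing {fname}")
    scaler = ScalerState.from_json((directory / "scaler.json").read_text())
    selector = SelectorState.from_json((directory / "selector.json").read_text())
    model = joblib.load(directory / "model.joblib")
    config = DescriptorConfig.from_json((directory / "config.json").read_text())
    meta = json.loads((directory / "metadata.json").read_text())
    families = tuple(meta.pop("families"))
    return ModelBundle(scaler, selector, model, config, families, meta)


def train_model(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    families: Iterable[str] = ("AC", "DC", "TC", "APAAC", "MB"),
    reduction: str = "kbest-chi2",
    k: int = 300,
    classifier: str = "MLP",
    n_folds: int = 3,
    seed: int = 0,
    config: Optional[DescriptorConfig] = None,
) -> Tuple[ModelBundle, Dict[str, float]]:
    """Train one configuration end to end and report its CV statistics.

    The default configuration is the headline model: Mix descriptors,
    chi-squared top-300 selection, MLP with one hidden layer of 20 units,
    3-fold stratified CV.
    """
    config = config or DescriptorConfig()
    fams = normalize_families(families)
    ds, scaler, report = prepare_dataset(pos_records, neg_records, fams, config, seed=seed)
    sel = fit_selector(ds, reduction, k if reduction != "none" else ds.features.shape[1], seed)
    reduced = LabeledDataset(transform(sel, ds.features), ds.labels)
    auroc_mean, auroc_sd, acc_mean, acc_sd = run_cv(
        reduced, ClassifierSpec(classifier, seed=seed), n_folds, seed
    )
    model = build_classifier(ClassifierSpec(classifier, seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(reduced.features.to_numpy(dtype=float), reduced.labels.to_numpy())
    cv = {
        "auroc_mean": auroc_mean, "auroc_sd": auroc_sd,
        "acc_mean": acc_mean, "acc_sd": acc_sd, "n_folds": n_folds,
    }
    bundle = ModelBundle(
        scaler=scaler,
        selector=sel,
        model=model,
        config=config,
        families=fams,
        metadata={
            "classifier": classifier, "reduction": reduction, "k": k,
            "seed": seed, "cv": cv, "clean_report": report,
        },
    )
    return bundle, cv
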