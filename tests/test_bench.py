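import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from bcpred.bench import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    build_classifier,
    load_bundle,
    pick_best,
    registry,
    run_cv,
    run_grid,
    save_bundle,
    train_model,
)
from bcpred.descriptors import featurize
from bcpred.prep import LabeledDataset

from oracles import oracle_auroc


def gaussian_ds(n=200, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0, 1, size=(half, 4)), rng.normal(separation, 1, size=(half, 4))]
    )
    y = np.array([0] * half + [1] * half)
    return LabeledDataset(pd.DataFrame(X, columns=list("abcd")), pd.Series(y))


class TestRegistry:
    def test_exactly_13_entries(self):
        specs = registry()
        assert len(specs) == 13
        assert [s.name for s in specs] == list(CLASSIFIER_NAMES)

    def test_mlp_single_hidden_layer_of_20(self):
        mlp = build_classifier(ClassifierSpec("MLP"))
        assert mlp.hidden_layer_sizes == (20,)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="SVM-linear"):
            build_classifier(ClassifierSpec("SVQ"))

    def test_all_members_expose_proba_interface(self):
        ds = gaussian_ds(n=40)
        X, y = ds.features.to_numpy(), ds.labels.to_numpy()
        for spec in registry(seed=1):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_classifier(spec).fit(X, y)
            proba = model.predict_proba(X)
            assert proba.shape == (40, 2)
            np.testing.assert_allclose(proba.sum(axis=1), 1, atol=1e-6)


class TestAurocAgainstConcordanceOracle:
    """The harness metric must equal pairwise concordance, ties = 0.5."""

    @pytest.mark.parametrize("trial", range(5))
    def test_toy_score_vectors(self, trial):
        rng = np.random.default_rng(trial)
        y = rng.integers(0, 2, size=20)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=20)
        # quantized scores force ties across groups; compare the
        # integer-valued concordance numerator 2*U so the check is exact
        scores = np.round(rng.uniform(0, 1, size=20), 1)
        n1, n0 = int((y == 1).sum()), int((y == 0).sum())
        expected = oracle_auroc(scores[y == 1], scores[y == 0])
        assert round(roc_auc_score(y, scores) * 2 * n1 * n0) == round(expected * 2 * n1 * n0)


class TestRunCV:
    def test_separable_gaussians_give_perfect_auroc(self):
        stats = run_cv(gaussian_ds(n=200, separation=6.0), ClassifierSpec("LDA"), 3, 0)
        assert stats[0] == 1.0

    def test_permuted_labels_near_half(self):
        ds = gaussian_ds(n=200, separation=6.0, seed=1)
        rng = np.random.default_rng(2)
        y_perm = pd.Series(rng.permutation(ds.labels.to_numpy()))
        null = LabeledDataset(ds.features, y_perm)
        stats = run_cv(null, ClassifierSpec("LDA"), 3, 0)
        assert 0.35 <= stats[0] <= 0.65

    def test_same_seed_identical(self):
        ds = gaussian_ds(n=100, separation=2.0)
        a = run_cv(ds, ClassifierSpec("RF", seed=4), 3, seed=4)
        b = run_cv(ds, ClassifierSpec("RF", seed=4), 3, seed=4)
        assert a == b

    @pytest.mark.parametrize("n_folds", [3, 5, 10])
    def test_fold_variants_report_mean_and_sd(self, n_folds):
        stats = run_cv(gaussian_ds(n=100, separation=2.0), ClassifierSpec("LDA"), n_folds, 0)
        assert 0 <= stats[0] <= 1 and stats[1] >= 0
        assert 0 <= stats[2] <= 1 and stats[3] >= 0


class TestRunGrid:
    def test_combinatorial_row_count_and_sorted(self, small_corpus):
        pos, neg = small_corpus
        table = run_grid(
            pos, neg,
            family_sets={"AC": ("AC",), "DC": ("DC",)},
            reductions=("kbest-chi2",),
            k_grid=(20,),
            classifiers=[ClassifierSpec(n) for n in ("NB", "LDA", "DT")],
            n_folds=3, seed=0,
        )
        assert len(table) == 6
        auroc = table["auroc_mean"].to_numpy()
        assert (np.diff(auroc) <= 1e-12).all()

    def test_rerun_identical_csv_bytes(self, small_corpus, tmp_path):
        pos, neg = small_corpus
        kwargs = dict(
            family_sets={"AC": ("AC",)}, reductions=("none",), k_grid=(),
            classifiers=[ClassifierSpec("LR", seed=3)], n_folds=3, seed=3,
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_grid(pos, neg, **kwargs).to_csv(p1, index=False)
        run_grid(pos, neg, **kwargs).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()


class TestPickBest:
    def make_table(self, rows):
        return pd.DataFrame(
            [
                {
                    "descriptor_set": "Mix", "reduction": "kbest-chi2", "k": r[2],
                    "classifier": c, "n_features": r[2], "auroc_mean": r[0],
                    "auroc_sd": r[1], "acc_mean": 0.9, "acc_sd": 0.01,
                    "n_folds": 3, "seed": 0, "error": "",
                }
                for c, r in rows.items()
            ]
        )

    def test_sd_breaks_auroc_tie(self):
        table = self.make_table({"MLP": (0.98, 0.0037, 300), "LR": (0.98, 0.0077, 300)})
        best, rationale = pick_best(table)
        assert best["classifier"] == "MLP"
        assert "MLP" in rationale

    def test_feature_count_breaks_remaining_tie(self):
        table = self.make_table({"A": (0.9, 0.01, 300), "B": (0.9, 0.01, 100)})
        best, _ = pick_best(table)
        assert best["n_features"] == 100

    def test_single_row(self):
        table = self.make_table({"NB": (0.7, 0.1, 20)})
        assert pick_best(table)[0]["classifier"] == "NB"

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            pick_best(self.make_table({}))


class TestModelBundle:
    def test_round_trip_predictions_bit_identical(self, small_corpus, small_bundle, tmp_path):
        pos, neg = small_corpus
        save_bundle(small_bundle, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        matrix = featurize(pos[:25] + neg[:25], small_bundle.families, small_bundle.config)
        a = small_bundle.predict_proba(matrix)
        b = loaded.predict_proba(matrix)
        assert (a == b).all()

    def test_metadata_records_provenance(self, small_bundle, tmp_path):
        save_bundle(small_bundle, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        assert loaded.families == ("AC", "DC")
        assert loaded.metadata["k"] == 50
        assert loaded.metadata["seed"] == 7
        assert "cv" in loaded.metadata

    def test_missing_scaler_file_errors(self, small_bundle, tmp_path):
        d = save_bundle(small_bundle, tmp_path / "bundle")
        (d / "scaler.json").unlink()
        with pytest.raises(FileNotFoundError, match="scaler.json"):
            load_bundle(d)


class TestTrainModel:
    def test_cv_stats_and_bundle_consistency(self, small_corpus):
        pos, neg = small_corpus
        bundle, cv = train_model(
            pos, neg, families=("AC",), reduction="none", k=0,
            classifier="LDA", n_folds=3, seed=1,
        )
        assert 0.5 < cv["auroc_mean"] <= 1.0  # delta=0.3 corpus is separable
        assert bundle.selector.mode == "none"
        matrix = featurize(pos + neg, bundle.families, bundle.config)
        proba = bundle.predict_proba(matrix)
        assert proba.shape == (len(pos) + len(neg),)
        assert np.all((proba >= 0) & (proba <= 1))
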