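"""Sub-band features, classification metrics and cross-validation."""

import numpy as np
import pandas as pd
import pytest
import pywt

from wavehar import (
    Segment,
    classification_metrics,
    compare_wavelets_classification,
    crossval_evaluate,
    feature_matrix,
    subband_features,
)
from wavehar.features import make_classifier
from sklearn.model_selection import StratifiedKFold


def test_feature_vector_dimension_and_names(rng):
    seg = Segment(samples=rng.normal(size=(125, 3)), label="walk")
    vec = subband_features(seg, "db5", 3)
    assert len(vec.values) == 4 * 8 * 3 == 96
    assert len(set(vec.names)) == 96
    assert vec.names[0] == "mean_n0_x"
    assert vec.label == "walk"


def test_subband_statistics_match_pywt_reference(rng):
    """Mean/RMS/variance per node agree with stats computed from an
    independent periodized decomposition."""
    x = rng.normal(size=(128, 3))
    seg = Segment(samples=x, label="a")
    vec = subband_features(seg, "db5", 1)
    values = dict(zip(vec.names, vec.values))
    for axis_i, axis in enumerate("xyz"):
        a, d = pywt.dwt(x[:, axis_i], "db5", mode="periodization")
        for node_i, node in enumerate((a, d)):
            m = node.size
            assert values[f"mean_n{node_i}_{axis}"] == pytest.approx(node.mean())
            assert values[f"rms_n{node_i}_{axis}"] == pytest.approx(
                np.sqrt(np.mean(node**2))
            )
            assert values[f"variance_n{node_i}_{axis}"] == pytest.approx(
                np.sum((node - node.mean()) ** 2) / (m - 1)
            )


def test_variance_uses_unbiased_denominator():
    # node [3, 4]: mean 3.5, RMS sqrt(12.5), variance 0.5 with m-1
    node = np.array([3.0, 4.0])
    assert node.mean() == 3.5
    assert np.sqrt(np.mean(node**2)) == pytest.approx(3.5355339)
    assert np.sum((node - node.mean()) ** 2) / (node.size - 1) == pytest.approx(0.5)
    # and the feature path at level 3 reproduces hand values on zeros
    seg = Segment(samples=np.zeros((125, 3)), label="z")
    vec = subband_features(seg, "haar", 3)
    stats = [v for n, v in zip(vec.names, vec.values) if not n.startswith("ratio")]
    assert np.allclose(stats, 0.0)


def test_degenerate_ratio_becomes_zero(caplog):
    seg = Segment(samples=np.zeros((125, 3)), label="z")
    vec = subband_features(seg, "haar", 3)
    ratios = [v for n, v in zip(vec.names, vec.values) if n.startswith("ratio")]
    assert np.allclose(ratios, 0.0)


def test_ratio_feature_is_pooled_per_axis(rng):
    from wavehar import energy_entropy_ratio, get_wavelet, wpt_decompose

    x = rng.normal(size=(125, 3))
    vec = subband_features(Segment(samples=x, label="a"), "sym5", 3)
    values = dict(zip(vec.names, vec.values))
    expected = energy_entropy_ratio(wpt_decompose(x[:, 0], get_wavelet("sym5"), 3))
    for node_i in range(8):
        assert values[f"ratio_n{node_i}_x"] == pytest.approx(expected)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = classification_metrics(["a", "b", "a", "b"], ["a", "b", "a", "b"])
        assert rep.balanced_accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert (rep.per_class[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_hand_computed_contingency(self):
        # class a: TP=2, FP=1, FN=1 -> P = R = F1 = 2/3
        rep = classification_metrics(
            ["a", "a", "a", "b", "b", "b"], ["a", "a", "b", "a", "b", "b"]
        )
        row = rep.per_class.loc["a"]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["f1"] == pytest.approx(2 / 3)

    def test_absent_class_scores_zero(self):
        rep = classification_metrics(["a", "a", "c"], ["a", "a", "a"])
        row = rep.per_class.loc["c"]
        assert (row[["precision", "recall", "f1"]] == 0.0).all()

    def test_balanced_accuracy_is_mean_recall_from_confusion(self, rng):
        y_true = rng.choice(list("abcd"), size=200)
        y_pred = rng.choice(list("abcd"), size=200)
        rep = classification_metrics(y_true, y_pred)
        cm = rep.confusion.to_numpy()
        recalls = np.diag(cm) / cm.sum(axis=1)
        assert rep.balanced_accuracy == pytest.approx(np.mean(recalls))
        assert cm.sum() == 200
        counts = pd.Series(y_true).value_counts().reindex(rep.confusion.index)
        assert (cm.sum(axis=1) == counts.to_numpy()).all()

    def test_macro_f1_invariant_to_relabelling(self, rng):
        y_true = rng.choice(list("abc"), size=120)
        y_pred = rng.choice(list("abc"), size=120)
        rep = classification_metrics(y_true, y_pred)
        swap = {"a": "c", "b": "a", "c": "b"}
        rep2 = classification_metrics(
            [swap[v] for v in y_true], [swap[v] for v in y_pred]
        )
        assert rep.macro_f1 == pytest.approx(rep2.macro_f1)
        assert rep.balanced_accuracy == pytest.approx(rep2.balanced_accuracy)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics([], [])


def gaussian_features(rng, n_per_class=60, n_classes=2, spread=8.0):
    rows, labels = [], []
    for c in range(n_classes):
        centre = spread * c
        rows.append(rng.normal(centre, 1.0, size=(n_per_class, 5)))
        labels += [f"class{c}"] * n_per_class
    frame = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(5)])
    frame["label"] = labels
    return frame


class TestCrossval:
    @pytest.mark.parametrize("clf", ["dt", "svm"])
    def test_separable_clouds_are_perfect(self, clf, rng):
        feats = gaussian_features(rng)
        rep = crossval_evaluate(feats, clf, k=10, seed=3)
        assert rep.balanced_accuracy == 1.0
        assert rep.n_folds == 10

    def test_shuffled_labels_score_at_chance(self, rng):
        feats = gaussian_features(rng, n_per_class=50, n_classes=4, spread=0.0)
        feats["label"] = rng.permutation(feats["label"].to_numpy())
        rep = crossval_evaluate(feats, "dt", k=10, seed=5)
        assert 0.15 <= rep.balanced_accuracy <= 0.35  # chance = 0.25

    def test_deterministic_given_seed(self, rng):
        feats = gaussian_features(rng, spread=2.0)
        a = crossval_evaluate(feats, "svm", k=10, seed=9)
        b = crossval_evaluate(feats, "svm", k=10, seed=9)
        assert a.balanced_accuracy == b.balanced_accuracy
        assert a.confusion.equals(b.confusion)

    def test_matches_explicit_per_fold_protocol(self, rng):
        """Pooled predictions equal a hand-written CV loop that fits the
        scaler strictly on training folds — no leakage shortcut."""
        feats = gaussian_features(rng, spread=1.5)
        y = feats["label"].to_numpy()
        X = feats.drop(columns="label").to_numpy(float)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=4)
        pred = np.empty_like(y)
        for train, test in skf.split(X, y):
            pipe = make_classifier("dt", seed=4)
            pipe.fit(X[train], y[train])
            pred[test] = pipe.predict(X[test])
        expected = classification_metrics(y, pred)
        rep = crossval_evaluate(feats, "dt", k=10, seed=4)
        assert rep.confusion.equals(expected.confusion)

    def test_small_class_shrinks_fold_count(self, rng, caplog):
        feats = gaussian_features(rng, n_per_class=6)
        import logging

        with caplog.at_level(logging.WARNING):
            rep = crossval_evaluate(feats, "dt", k=10, seed=0)
        assert rep.n_folds == 6
        assert "fewer than" in caplog.text

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            crossval_evaluate(gaussian_features(rng), "dt", k=1, seed=0)


class TestCompareWavelets:
    def test_single_pair_matches_crossval(self, small_benchmark):
        segs = small_benchmark
        table = compare_wavelets_classification(segs, ["haar"], ("dt",), k=5, seed=2)
        assert table.shape[0] == 1
        feats = feature_matrix(segs, "haar", 3)
        rep = crossval_evaluate(feats, "dt", k=5, seed=2)
        assert table.loc[0, "balanced_accuracy_dt"] == pytest.approx(
            100 * rep.balanced_accuracy
        )
        assert table.loc[0, "macro_f1_dt"] == pytest.approx(rep.macro_f1)

    def test_repeat_is_identical(self, small_benchmark):
        segs = small_benchmark[:120]
        a = compare_wavelets_classification(segs, ["haar"], ("dt",), k=4, seed=8)
        b = compare_wavelets_classification(segs, ["haar"], ("dt",), k=4, seed=8)
        assert a.equals(b)

    def test_requires_inputs(self, small_benchmark):
        with pytest.raises(ValueError):
            compare_wavelets_classification(small_benchmark, [], ("dt",))
        with pytest.raises(ValueError):
            compare_wavelets_classification(small_benchmark, ["haar"], ())
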