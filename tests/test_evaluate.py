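"""Confusion-matrix metrics, classifier harness and k-fold summaries."""

import numpy as np
import pandas as pd
import pytest

import ecgwave as ew


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a"]
        cm = ew.confusion_matrix(y, y, ("a", "b", "c"))
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_hand_counted_example(self):
        cm = ew.confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ("a", "b"))
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_row_sums_equal_true_frequencies(self):
        rng = np.random.default_rng(0)
        classes = ("x", "y", "z")
        y_true = rng.choice(classes, 60)
        y_pred = rng.choice(classes, 60)
        cm = ew.confusion_matrix(y_true, y_pred, classes)
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == np.sum(y_true == c)
        assert cm.total == 60

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ew.confusion_matrix(["a"], ["q"], ("a", "b"))


class TestClassReport:
    def test_sensitivity_from_raw_counts(self):
        """Worked sensitivity values from per-class counts: 35/41 →
        85.4%, 87/95 → 91.6%, 25/41 → 61.0%, 39/41 → 95.1%, 1/41 → 2.4%."""
        cases = [(35, 41, 85.4), (87, 95, 91.6), (25, 41, 61.0),
                 (39, 41, 95.1), (1, 41, 2.4)]
        for correct, total, expected in cases:
            counts = np.array([[correct, total - correct], [0, 10]])
            cm = ew.ConfusionMatrix(classes=("pos", "neg"), counts=counts)
            report = ew.class_report(cm)
            assert round(report.sensitivity["pos"], 1) == expected
            assert round(report.misclassification["pos"], 1) == round(
                100 - expected, 1)

    def test_accuracy_is_trace_over_total(self):
        counts = np.array([[35, 3, 3], [4, 87, 4], [1, 1, 96]])
        cm = ew.ConfusionMatrix(classes=("b", "n", "t"), counts=counts)
        report = ew.class_report(cm)
        assert report.accuracy == pytest.approx(100 * (35 + 87 + 96) / counts.sum())

    def test_empty_predicted_column_flagged(self):
        counts = np.array([[5, 0], [3, 0]])
        cm = ew.ConfusionMatrix(classes=("a", "b"), counts=counts)
        report = ew.class_report(cm)
        assert report.precision["b"] == 0.0
        assert "b" in report.undefined_precision

    def test_matches_brute_force_from_labels(self):
        """Report formulas agree with direct recounting from the raw
        label lists for random confusion structures up to 10 classes."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            k = int(rng.integers(2, 11))
            classes = tuple(f"c{i}" for i in range(k))
            y_true = list(rng.choice(classes, 200))
            # ensure every class appears as a true label
            y_true[:k] = list(classes)
            y_pred = list(rng.choice(classes, 200))
            cm = ew.confusion_matrix(y_true, y_pred, classes)
            report = ew.class_report(cm)
            acc = 100 * np.mean([t == p for t, p in zip(y_true, y_pred)])
            assert report.accuracy == pytest.approx(acc)
            for c in classes:
                n_true = sum(t == c for t in y_true)
                n_hit = sum(t == p == c for t, p in zip(y_true, y_pred))
                assert report.sensitivity[c] == pytest.approx(100 * n_hit / n_true)

    def test_accuracy_invariant_under_class_permutation(self):
        counts = np.array([[35, 3, 3], [4, 87, 4], [1, 1, 96]])
        cm = ew.ConfusionMatrix(classes=("b", "n", "t"), counts=counts)
        perm = [2, 0, 1]
        cm_p = ew.ConfusionMatrix(classes=tuple(np.array(cm.classes)[perm]),
                                  counts=counts[np.ix_(perm, perm)])
        assert ew.class_report(cm).accuracy == pytest.approx(
            ew.class_report(cm_p).accuracy)


def synthetic_image_manifest(tmp_path, n_per_class=12, size=224, seed=0):
    """Linearly separable 3-class image set: each class has a distinct
    mean intensity with small seeded noise."""
    from PIL import Image

    rng = np.random.default_rng(seed)
    rows = []
    for level, cls in zip((40, 128, 216), ("bradycardia", "normal", "tachycardia")):
        for i in range(n_per_class):
            pixels = np.clip(level + rng.normal(0, 8, (size, size, 3)), 0,
                             255).astype(np.uint8)
            path = tmp_path / f"{cls}_{i}.png"
            Image.fromarray(pixels).save(path)
            rows.append({"path": str(path), "class": cls, "wave": "T",
                         "representation": "scalogram",
                         "record_id": f"{cls}{i}", "beat": i})
    return pd.DataFrame(rows)


class TestClassifierHarness:
    def test_separable_classes_learned(self, tmp_path):
        manifest = synthetic_image_manifest(tmp_path)
        train, test = ew.split_dataset(manifest, 0.7, seed=0)
        model = ew.train_classifier(train, seed=0)
        _, report_train = ew.evaluate(model, train)
        assert report_train.accuracy >= 99.0
        _, report = ew.evaluate(model, test)
        assert report.accuracy == 100.0

    def test_fixed_seed_identical_predictions(self, tmp_path):
        manifest = synthetic_image_manifest(tmp_path)
        train, test = ew.split_dataset(manifest, 0.7, seed=0)
        a = ew.train_classifier(train, {"kind": "mlp"}, seed=3)
        b = ew.train_classifier(train, {"kind": "mlp"}, seed=3)
        assert np.array_equal(a.predict_paths(test["path"]),
                              b.predict_paths(test["path"]))

    def test_shuffled_training_order_same_report(self, tmp_path):
        manifest = synthetic_image_manifest(tmp_path)
        train, test = ew.split_dataset(manifest, 0.7, seed=0)
        shuffled = train.sample(frac=1.0, random_state=9)
        a = ew.train_classifier(train, seed=0)
        b = ew.train_classifier(shuffled, seed=0)
        _, ra = ew.evaluate(a, test)
        _, rb = ew.evaluate(b, test)
        assert ra.accuracy == pytest.approx(rb.accuracy, abs=1e-6)

    def test_single_class_training_rejected(self, tmp_path):
        manifest = synthetic_image_manifest(tmp_path, n_per_class=3)
        only = manifest[manifest["class"] == "normal"]
        with pytest.raises(ValueError):
            ew.train_classifier(only)

    def test_missing_image_rejected_with_path(self, tmp_path):
        manifest = synthetic_image_manifest(tmp_path, n_per_class=3)
        model = ew.train_classifier(manifest, seed=0)
        bad = manifest.copy()
        bad.loc[bad.index[0], "path"] = str(tmp_path / "gone.png")
        with pytest.raises(FileNotFoundError, match="gone.png"):
            ew.evaluate(model, bad)


class TestKFoldSummary:
    def _report(self, acc):
        return ew.ClassReport(classes=("a", "b"),
                              sensitivity={"a": acc, "b": acc},
                              precision={"a": acc, "b": acc},
                              accuracy=acc,
                              misclassification={"a": 100 - acc, "b": 100 - acc})

    def test_identical_reports_zero_std(self):
        summary = ew.summarize_kfold([self._report(95.0)] * 3)
        assert summary.accuracy_mean == 95.0 and summary.accuracy_std == 0.0

    def test_sample_std_of_two_reports(self):
        summary = ew.summarize_kfold([self._report(96.0), self._report(98.0)])
        assert summary.accuracy_mean == pytest.approx(97.0)
        assert summary.accuracy_std == pytest.approx(np.sqrt(2.0))

    def test_mean_bounded_by_inputs(self):
        accs = [91.0, 94.5, 99.0]
        summary = ew.summarize_kfold([self._report(a) for a in accs])
        assert min(accs) <= summary.accuracy_mean <= max(accs)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            ew.summarize_kfold([self._report(90.0)])
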