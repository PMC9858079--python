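"""Classifier training harness and confusion-matrix evaluation.

The evaluation protocol mirrors standard rhythm-classification
reporting: a confusion matrix C with C[i, j] = count of class-i items
predicted as class j, per-class sensitivity (recall, 100·C[ii]/row sum)
and precision (PPV, 100·C[ii]/column sum), overall accuracy
(100·trace/total) and the per-class misclassification rate
(100 − sensitivity).  K-fold runs are summarized as mean ± sample
standard deviation of macro sensitivity, macro precision and accuracy.

The classifier itself is pluggable behind a tiny ``model_spec``
mapping; the default is a deterministic scikit-learn pipeline —
grayscale-downsampled pixel features, standardized, into multinomial
logistic regression — which is ample for separating rate classes in
time-frequency images at desk scale.  Any object exposing
``fit(X, y)`` / ``predict(X)`` over flattened image features can be
plugged in instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

FEATURE_SIZE = 24  # images are downsampled to FEATURE_SIZE² grayscale features


@dataclass
class ConfusionMatrix:
    """Counts matrix over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square |classes| matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(y_true, y_pred,
                     classes: tuple[str, ...] | list[str]) -> ConfusionMatrix:
    """Count predictions into a confusion matrix with a fixed class order."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} "
                             f"not in class order {tuple(classes)}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


@dataclass
class ClassReport:
    """Per-class sensitivity/precision (%), overall accuracy (%)."""

    classes: tuple[str, ...]
    sensitivity: dict[str, float]
    precision: dict[str, float]
    accuracy: float
    misclassification: dict[str, float]
    undefined_precision: tuple[str, ...] = ()

    @property
    def macro_sensitivity(self) -> float:
        return float(np.mean([self.sensitivity[c] for c in self.classes]))

    @property
    def macro_precision(self) -> float:
        return float(np.mean([self.precision[c] for c in self.classes]))

    def as_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Report table with percentages rounded for presentation."""
        return pd.DataFrame({
            "sensitivity_%": {c: round(self.sensitivity[c], decimals)
                              for c in self.classes},
            "precision_%": {c: round(self.precision[c], decimals)
                            for c in self.classes},
            "misclassification_%": {c: round(self.misclassification[c], decimals)
                                    for c in self.classes},
        })


def class_report(cm: ConfusionMatrix) -> ClassReport:
    """Sensitivity, precision, accuracy and misclassification rate from C.

    sensitivity_i = 100·C[ii]/Σ_j C[ij]; precision_i = 100·C[ii]/Σ_j C[ji];
    accuracy = 100·trace(C)/ΣC.  A class never predicted has its
    precision reported as 0 and is flagged in ``undefined_precision``.
    """
    C = cm.counts
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    if (row == 0).any():
        empty = [c for c, n in zip(cm.classes, row) if n == 0]
        raise ValueError(f"classes {empty} have no true items")
    sens, prec, misc = {}, {}, {}
    undefined = []
    for i, c in enumerate(cm.classes):
        sens[c] = 100.0 * C[i, i] / row[i]
        if col[i] == 0:
            prec[c] = 0.0
            undefined.append(c)
        else:
            prec[c] = 100.0 * C[i, i] / col[i]
        misc[c] = 100.0 - sens[c]
    accuracy = 100.0 * np.trace(C) / C.sum()
    return ClassReport(classes=cm.classes, sensitivity=sens, precision=prec,
                       accuracy=float(accuracy), misclassification=misc,
                       undefined_precision=tuple(undefined))


# ----------------------------------------------------------------------
# image features and models
# ----------------------------------------------------------------------
def image_features(source: str | Path | np.ndarray,
                   size: int = FEATURE_SIZE) -> np.ndarray:
    """Flattened grayscale features of one image (path or HxWx3 array)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"image file not found: {path}")
        img = Image.open(path).convert("L")
    else:
        img = Image.fromarray(np.asarray(source, dtype=np.uint8)).convert("L")
    img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=float).ravel() / 255.0


def _manifest_features(manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([image_features(p) for p in manifest["path"]])
    y = manifest["class"].to_numpy()
    return X, y


def make_model(model_spec: dict | None = None, seed: int = 0):
    """Build an estimator from a model_spec mapping.

    ``{"kind": "logreg"}`` (default) — standardized multinomial logistic
    regression; ``{"kind": "mlp", "hidden": (64,)}`` — a small
    multilayer perceptron.  Extra keys pass through to the estimator.
    """
    spec = dict(model_spec or {})
    kind = spec.pop("kind", "logreg")
    if kind == "logreg":
        est = LogisticRegression(max_iter=int(spec.pop("max_iter", 2000)),
                                 C=float(spec.pop("C", 1.0)), **spec)
    elif kind == "mlp":
        est = MLPClassifier(hidden_layer_sizes=tuple(spec.pop("hidden", (64,))),
                            max_iter=int(spec.pop("max_iter", 500)),
                            random_state=seed, **spec)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass
class TrainedModel:
    """A fitted pipeline with its class order and feature extractor."""

    pipeline: Pipeline
    classes: tuple[str, ...]

    def predict_paths(self, paths) -> np.ndarray:
        X = np.stack([image_features(p) for p in paths])
        return self.pipeline.predict(X)

    def predict(self, image) -> str:
        """Predict the class of a single image (path or pixel array)."""
        return str(self.pipeline.predict(image_features(image)[None, :])[0])


def train_classifier(train_manifest: pd.DataFrame,
                     model_spec: dict | None = None,
                     seed: int = 0) -> TrainedModel:
    """Fit the pluggable classifier on a manifest of labeled images.

    Deterministic for a fixed seed (the default logistic-regression
    pipeline is deterministic outright).  A single-class training set is
    rejected.
    """
    if len(train_manifest) == 0:
        raise ValueError("empty training manifest")
    X, y = _manifest_features(train_manifest)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least two classes")
    pipe = make_model(model_spec, seed=seed)
    pipe.fit(X, y)
    return TrainedModel(pipeline=pipe, classes=tuple(pipe.classes_))


def evaluate(model: TrainedModel, test_manifest: pd.DataFrame,
             class_order: tuple[str, ...] | None = None
             ) -> tuple[ConfusionMatrix, ClassReport]:
    """Predict every test image and derive the confusion matrix + report."""
    if len(test_manifest) == 0:
        raise ValueError("empty test manifest")
    y_true = test_manifest["class"].to_numpy()
    y_pred = model.predict_paths(test_manifest["path"])
    classes = class_order or tuple(sorted(set(y_true) | set(model.classes)))
    cm = confusion_matrix(y_true, y_pred, classes)
    return cm, class_report(cm)


@dataclass
class KFoldSummary:
    """Mean ± sample std of metrics across folds (percent units)."""

    sensitivity_mean: float
    sensitivity_std: float
    precision_mean: float
    precision_std: float
    accuracy_mean: float
    accuracy_std: float
    n_folds: int

    def as_frame(self, decimals: int = 2) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": [round(self.sensitivity_mean, decimals),
                     round(self.precision_mean, decimals),
                     round(self.accuracy_mean, decimals)],
            "std": [round(self.sensitivity_std, decimals),
                    round(self.precision_std, decimals),
                    round(self.accuracy_std, decimals)],
        }, index=["sensitivity_%", "precision_%", "accuracy_%"])


def summarize_kfold(reports: list[ClassReport]) -> KFoldSummary:
    """Mean and sample (n−1) standard deviation of fold metrics."""
    if len(reports) < 2:
        raise ValueError("need at least two fold reports to summarize")
    sens = np.array([r.macro_sensitivity for r in reports])
    prec = np.array([r.macro_precision for r in reports])
    acc = np.array([r.accuracy for r in reports])
    return KFoldSummary(
        sensitivity_mean=float(sens.mean()), sensitivity_std=float(sens.std(ddof=1)),
        precision_mean=float(prec.mean()), precision_std=float(prec.std(ddof=1)),
        accuracy_mean=float(acc.mean()), accuracy_std=float(acc.std(ddof=1)),
        n_folds=len(reports),
    )


def run_kfold(manifest: pd.DataFrame, k: int = 5, seed: int = 0,
              model_spec: dict | None = None
              ) -> tuple[list[ClassReport], KFoldSummary]:
    """Train/evaluate across stratified folds and summarize."""
    from .imaging import kfold_split

    reports = []
    for i, (train, test) in enumerate(kfold_split(manifest, k=k, seed=seed)):
        model = train_classifier(train, model_spec, seed=seed + i)
        _, report = evaluate(model, test)
        reports.append(report)
    return reports, summarize_kfold(reports)
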