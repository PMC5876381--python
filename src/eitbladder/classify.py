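"""Classifier training and stratified k-fold evaluation.

Three classifier families are supported: linear SVM, cubic
(third-order polynomial kernel) SVM, and cosine-distance k-NN with
k = 10 and no distance weighting.  Every predictor (one of the 928
voltages) is standardised with statistics fitted on the training fold
only.  Metrics follow the balanced convention: sensitivity is the
correct-prediction rate on 'full', specificity on 'not full', and
accuracy is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import FoldSplit, LabeledDataset

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "Standardizer",
    "TrainedClassifier",
    "MetricsReport",
    "FoldResult",
    "fit_standardizer",
    "apply_standardizer",
    "train_classifier",
    "evaluate",
    "run_10fold",
    "misclassification_by_factor",
    "two_threshold_report",
]

CLASSIFIER_KINDS = ("linear_svm", "cubic_svm", "cosine_knn")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    k_neighbours: int = 10
    distance_weighting: bool = False
    regularization: float = 1.0
    kernel_degree: int = 3
    random_state: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.k_neighbours < 1:
            raise ValueError("k_neighbours must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if self.kind == "cubic_svm" and self.kernel_degree != 3:
            raise ValueError("cubic_svm requires kernel_degree = 3")


# ---------------------------------------------------------------------------
# per-predictor standardisation
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Location/scale per predictor, fitted on training data (sample sd)."""

    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.scale + self.mean


def fit_standardizer(X: np.ndarray) -> Standardizer:
    X = np.asarray(X, float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 training observations")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= 1e-300
    scale = np.where(constant, 1.0, sd)
    return Standardizer(mean=mean, scale=scale, constant_mask=constant)


def apply_standardizer(std: Standardizer, X: np.ndarray) -> np.ndarray:
    return std.transform(X)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    standardizer: Standardizer
    estimator: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self.standardizer.transform(X)).astype(np.int8)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = self.standardizer.transform(X)
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(Z)
        proba = self.estimator.predict_proba(Z)
        return proba[:, 1] - proba[:, 0]


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "linear_svm":
        return SVC(kernel="linear", C=spec.regularization, cache_size=500,
                   random_state=spec.random_state)
    if spec.kind == "cubic_svm":
        # (x.x'/p + 1)^3 on standardised features: the auto kernel scale
        # keeps SMO well-conditioned with ~1e3 predictors
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale",
                   C=spec.regularization, cache_size=500,
                   random_state=spec.random_state)
    weights = "distance" if spec.distance_weighting else "uniform"
    return KNeighborsClassifier(n_neighbors=spec.k_neighbours, metric="cosine",
                                algorithm="brute", weights=weights)


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedClassifier:
    """Standardise the training observations, then fit the classifier.

    ``y`` uses the integer label codes (1 = full).  Raises on a
    single-class training set.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    std = fit_standardizer(X)
    est = _make_estimator(spec)
    est.fit(std.transform(X), y)
    return TrainedClassifier(spec=spec, standardizer=std, estimator=est)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold sensitivity/specificity/accuracy plus pooled confusion counts.

    ``accuracy = (sensitivity + specificity) / 2`` per fold (balanced
    accuracy).  A metric whose class is absent from a test set is NaN,
    never silently zero.  Aggregates are mean and sample sd over folds.
    """

    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    confusion: dict  # pooled over folds: tp, fn, tn, fp

    def _agg(self, x):
        x = np.asarray(x, float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return mean, sd

    @property
    def mean_sensitivity(self):
        return self._agg(self.sensitivity)[0]

    @property
    def mean_specificity(self):
        return self._agg(self.specificity)[0]

    @property
    def mean_accuracy(self):
        return self._agg(self.accuracy)[0]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, vals in (("sensitivity", self.sensitivity),
                           ("specificity", self.specificity),
                           ("accuracy", self.accuracy)):
            m, s = self._agg(vals)
            rows.append((name, m, s))
        return pd.DataFrame(rows, columns=["metric", "mean", "sd"])

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "MetricsReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        acc = (sens + spec) / 2.0
        return MetricsReport(sensitivity=np.array([sens]),
                             specificity=np.array([spec]),
                             accuracy=np.array([acc]),
                             confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp})

    @staticmethod
    def combine(parts: list["MetricsReport"]) -> "MetricsReport":
        conf = {k: sum(p.confusion[k] for p in parts) for k in ("tp", "fn", "tn", "fp")}
        return MetricsReport(
            sensitivity=np.concatenate([p.sensitivity for p in parts]),
            specificity=np.concatenate([p.specificity for p in parts]),
            accuracy=np.concatenate([p.accuracy for p in parts]),
            confusion=conf)


def evaluate(model: TrainedClassifier, X: np.ndarray, y: np.ndarray) -> MetricsReport:
    """Single-test-set metrics for a trained classifier."""
    if len(X) == 0:
        raise ValueError("empty test set")
    return MetricsReport.from_predictions(y, model.predict(X))


# ---------------------------------------------------------------------------
# k-fold driver and misclassification analysis
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    """Aggregate of one classifier kind over all folds."""

    spec: ClassifierSpec
    metrics: MetricsReport
    misclassified: np.ndarray          # global dataset indices
    models: list = field(default_factory=list)

    @property
    def error_percent(self) -> float:
        """Balanced error, 100 - mean balanced accuracy, in percent."""
        return 100.0 * (1.0 - self.metrics.mean_accuracy)


def run_10fold(dataset: LabeledDataset, folds: FoldSplit,
               specs: list[ClassifierSpec], keep_models: bool = False) -> dict:
    """Train/test every classifier spec on every fold.

    Returns ``{kind: FoldResult}`` with per-fold metric triples, pooled
    misclassified observation indices, and (optionally) the 10 trained
    models per kind for reuse on withheld data.
    """
    results = {}
    for spec in specs:
        reports, wrong, models = [], [], []
        for f in range(folds.n_folds):
            test_idx = np.asarray(folds.test_indices[f])
            train_idx = folds.train_indices(f, dataset.n_obs)
            try:
                model = train_classifier(spec, dataset.frames[train_idx],
                                         dataset.labels[train_idx])
            except Exception as exc:
                raise RuntimeError(f"fold {f}: training failed: {exc}") from exc
            pred = model.predict(dataset.frames[test_idx])
            reports.append(MetricsReport.from_predictions(dataset.labels[test_idx], pred))
            wrong.append(test_idx[pred != dataset.labels[test_idx]])
            if keep_models:
                models.append(model)
        results[spec.kind] = FoldResult(
            spec=spec, metrics=MetricsReport.combine(reports),
            misclassified=np.sort(np.concatenate(wrong)), models=models)
    return results


_FACTOR_COLUMNS = {"volume": "volume_ml", "conductivity": "sigma_urine",
                   "boundary": "boundary", "snr": "snr_db"}


def misclassification_by_factor(result: FoldResult, dataset: LabeledDataset,
                                factor: str) -> pd.Series:
    """Misclassified observations per factor level, as percent of test size.

    Counts are averaged over the fold classifiers and normalised by the
    (mean) test-set size, so the histogram sums to the overall
    misclassification percentage.  Ideal frames count under their
    dataset's SNR for the 'snr' factor.
    """
    if factor not in _FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {sorted(_FACTOR_COLUMNS)}")
    col = _FACTOR_COLUMNS[factor]
    values = dataset.meta[col]
    if factor == "snr":
        values = values.fillna(dataset.provenance.get("snr_db", np.nan))
    levels = np.sort(values.unique())
    counts = values.iloc[result.misclassified].value_counts()
    hist = pd.Series([float(counts.get(lv, 0)) for lv in levels], index=levels,
                     name="misclassified_percent")
    return hist / dataset.n_obs * 100.0


def two_threshold_report(result: FoldResult, dataset: LabeledDataset,
                         low_ml: float = 240.0, high_ml: float = 360.0) -> dict:
    """Correct-classification rates outside an uncertainty band.

    Reports how reliably volumes at or below ``low_ml`` are called
    not-full and volumes at or above ``high_ml`` full, supporting a
    two-threshold alerting scheme with an uncertain region between.
    """
    vol = dataset.meta["volume_ml"].to_numpy()
    wrong = np.zeros(dataset.n_obs, bool)
    wrong[result.misclassified] = True
    out = {}
    for name, mask in (("below_low_correct", vol <= low_ml),
                       ("above_high_correct", vol >= high_ml)):
        out[name] = float(1.0 - wrong[mask].mean()) if mask.any() else float("nan")
    out["low_ml"], out["high_ml"] = low_ml, high_ml
    return out
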