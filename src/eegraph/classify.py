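"""Benchmarking six standard classifiers on selected graph-measure features.

The feature set mirrors the screening scenario the pipeline targets: the
graph measures that discriminated the groups (e.g. beta-band modularity and
gamma-band radius) plus two pieces of routine clinical information (sex and
MMSE total score).  Validation uses stratified random 70/30 train/test
splits repeated 10 times under a fixed master seed; feature standardisation
is fit on each training fold only (no leakage).

Confusion counts are pooled over the repeats (micro-average) and converted
to the four confusion-matrix metrics

    precision = TP / (TP + FP)          recall   = TP / (TP + FN)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 * precision * recall / (precision + recall),

with zero denominators reported as 0 with a warning.  ROC AUC is computed
from test-fold scores; the report carries both the pooled metrics and the
per-repeat values, since reasonable aggregations differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import CovariateTable, PipelineConfig, logger

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "CLASSIFIER_NAMES",
    "build_features",
    "make_classifier",
    "metric_from_confusion",
    "evaluate_classifiers",
    "reports_to_frame",
]

CLASSIFIER_NAMES: tuple[str, ...] = (
    "logistic_regression",
    "svm",
    "random_forest",
    "gradient_boosting",
    "neural_network",
    "naive_bayes",
)


@dataclass
class FeatureMatrix:
    """Subjects × named features plus a binary label vector.

    ``y`` codes the second group level (the "positive" class) as 1.
    """

    X: pd.DataFrame
    y: np.ndarray
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.X.to_numpy(float))):
            raise ValueError("feature matrix contains non-finite values")
        self.y = np.asarray(self.y, dtype=int)
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("label vector must contain both classes")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


@dataclass
class ClassificationReport:
    """Pooled confusion counts, the four metrics, AUC, and per-repeat values."""

    classifier: str
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    per_repeat: pd.DataFrame = field(repr=False, default=None)


def build_features(
    metrics: pd.DataFrame,
    covariates: CovariateTable,
    selected: Sequence[str],
) -> FeatureMatrix:
    """Assemble a feature matrix from graph measures and covariates.

    ``selected`` names are either covariate columns (``sex``, ``mmse``) or
    ``<measure>_<band>`` combinations, e.g. ``modularity_beta`` or
    ``radius_gamma``.  Every selected feature must be available for every
    subject.  Standardisation is *not* applied here; it happens inside the
    evaluation loop, fit on training folds only.
    """
    wide = metrics.pivot_table(index="subject_id", columns=["measure", "band"], values="value")
    cov = covariates.frame.set_index("subject_id")
    missing_subjects = set(wide.index) ^ set(cov.index)
    if missing_subjects:
        raise ValueError(
            f"subject mismatch between metrics and covariates: {sorted(missing_subjects)[:5]}"
        )
    cov = cov.loc[wide.index]
    cols = {}
    for name in selected:
        if name in cov.columns:
            vals = cov[name]
            if name == "sex" and not pd.api.types.is_numeric_dtype(vals):
                vals = vals.astype("category").cat.codes
            cols[name] = vals.to_numpy(float)
            continue
        measure, _, band = name.rpartition("_")
        if measure and (measure, band) in wide.columns:
            cols[name] = wide[(measure, band)].to_numpy(float)
            continue
        raise KeyError(
            f"feature {name!r} is neither a covariate column nor an available "
            "measure_band combination"
        )
    neg, pos = covariates.require_two_groups()
    y = (cov["group"] == pos).to_numpy(int)
    X = pd.DataFrame(cols, index=wide.index)
    return FeatureMatrix(X=X, y=y, positive_label=str(pos), negative_label=str(neg))


def metric_from_confusion(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float, float]:
    """(precision, recall, accuracy, F1) from confusion counts.

    Undefined ratios (zero denominator) are reported as 0 with a warning;
    all-zero counts raise ``ValueError``.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("metric_from_confusion: %s undefined (0/0); reporting 0", name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    accuracy = (tp + tn) / sum(counts)
    f1 = ratio(2 * precision * recall, precision + recall, "F1")
    return precision, recall, accuracy, f1


def make_classifier(name: str, n_features: int, seed: int):
    """One of the six benchmark classifiers, wrapped with a training-fold
    scaler.  Hyperparameters are fixed, documented defaults (reproducibility
    over tuning): linear-kernel SVM, 100-tree random forest, one hidden
    layer of 2 × n_features units, Gaussian naive Bayes, default-depth
    gradient boosting."""
    rs = seed % (2**31)
    estimators = {
        "logistic_regression": lambda: LogisticRegression(max_iter=1000, random_state=rs),
        "svm": lambda: SVC(kernel="linear", random_state=rs),
        "random_forest": lambda: RandomForestClassifier(n_estimators=100, random_state=rs),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=rs),
        # hidden width floored at 4: one or two ReLU units can all go dead
        # on a 1-2 feature problem, collapsing the network to a constant
        "neural_network": lambda: MLPClassifier(
            hidden_layer_sizes=(max(4, 2 * n_features),), solver="lbfgs",
            max_iter=2000, random_state=rs,
        ),
        "naive_bayes": lambda: GaussianNB(),
    }
    if name not in estimators:
        raise KeyError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    return make_pipeline(StandardScaler(), estimators[name]())


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate_classifiers(
    features: FeatureMatrix,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
) -> list[ClassificationReport]:
    """Evaluate the benchmark classifiers under repeated stratified splits.

    All classifiers see the identical ``n_repeats`` stratified
    ``train_fraction`` splits drawn under the master seed, so their metrics
    are comparable.  Returns one :class:`ClassificationReport` per
    classifier.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    y = features.y
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = features.X.to_numpy(float)
    splitter = StratifiedShuffleSplit(
        n_splits=config.n_repeats,
        train_size=config.train_fraction,
        random_state=seed % (2**31),
    )
    splits = list(splitter.split(X, y))
    reports = []
    for name in classifiers:
        tp = fp = tn = fn = 0
        per_repeat = []
        for rep, (tr, te) in enumerate(splits):
            model = make_classifier(name, X.shape[1], seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            score = _scores(model, X[te])
            r_tp = int(np.sum((pred == 1) & (y[te] == 1)))
            r_fp = int(np.sum((pred == 1) & (y[te] == 0)))
            r_tn = int(np.sum((pred == 0) & (y[te] == 0)))
            r_fn = int(np.sum((pred == 0) & (y[te] == 1)))
            tp, fp, tn, fn = tp + r_tp, fp + r_fp, tn + r_tn, fn + r_fn
            prec, rec, acc, f1 = metric_from_confusion(r_tp, r_fp, r_tn, r_fn)
            auc = float(roc_auc_score(y[te], score))
            per_repeat.append(
                {"repeat": rep, "tp": r_tp, "fp": r_fp, "tn": r_tn, "fn": r_fn,
                 "precision": prec, "recall": rec, "accuracy": acc, "f1": f1, "auc": auc}
            )
        prec, rec, acc, f1 = metric_from_confusion(tp, fp, tn, fn)
        rep_frame = pd.DataFrame(per_repeat)
        reports.append(
            ClassificationReport(
                classifier=name, tp=tp, fp=fp, tn=tn, fn=fn,
                precision=prec, recall=rec, accuracy=acc, f1=f1,
                auc=float(rep_frame["auc"].mean()),
                per_repeat=rep_frame,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[ClassificationReport]) -> pd.DataFrame:
    """Summary table: one row per classifier."""
    return pd.DataFrame(
        [
            {
                "classifier": r.classifier,
                "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                "precision": r.precision, "recall": r.recall,
                "accuracy": r.accuracy, "f1": r.f1, "auc": r.auc,
            }
            for r in reports
        ]
    )
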