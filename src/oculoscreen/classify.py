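"""Leave-one-out screening classification, attribution and ablation.

The cohort is a feature matrix (subjects x F1..F16) with binary labels —
``patient`` is the positive class throughout.  Evaluation is leave-one-out
cross-validation (LOOCV): each subject is predicted by a model trained on
all others, and the pooled predictions form one confusion matrix.  When raw
series are supplied instead of a precomputed matrix, the normal standard
curve (and with it features F11-F16) is recomputed inside every fold from
the training subjects only, so no information about the held-out subject
leaks into its own features.

Eight classical model families are supported: random forest (RF), logistic
regression (LR), decision tree (DT), support-vector machine (SVM),
k-nearest neighbors (kNN), Gaussian naive Bayes (NB), gradient-boosted
trees (GBDT) and AdaBoost (AB).  Scale-sensitive families (LR, SVM, kNN)
are standardized fold-wise inside an sklearn pipeline.

Feature attribution uses a seeded Monte-Carlo estimate of Shapley values of
the model's patient-probability output, with the cohort itself as the
background distribution; per-feature weights are normalized mean absolute
attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigError, EmptyReportError
from .features import FEATURE_NAMES, GazeFeaturizer, SubjectSeries

POSITIVE_LABEL = "patient"
NEGATIVE_LABEL = "normal"

MODEL_FAMILIES = ("rf", "lr", "dt", "svm", "knn", "nb", "gbdt", "ab")

#: probability threshold above which (inclusive) a subject is called patient;
#: ties favor screening sensitivity
DECISION_THRESHOLD = 0.5


def make_model(family: str, seed: int = 0):
    """Fixed, documented default estimator for one model family."""
    family = family.lower()
    if family == "rf":
        # balanced class weights keep the forest unbiased under the slight
        # class imbalance every leave-one-out training fold has
        return RandomForestClassifier(
            n_estimators=100, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if family == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    if family == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if family == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
        )
    if family == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if family == "nb":
        return GaussianNB()
    if family == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if family == "ab":
        return AdaBoostClassifier(random_state=seed)
    raise ConfigError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


@dataclass
class ClassificationReport:
    """Pooled LOOCV confusion matrix plus derived metrics for one model."""

    model_family: str
    tp: int
    fn: int
    fp: int
    tn: int
    seed: int = 0
    n_abstained: int = 0
    feature_subset: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_subjects

    def metrics(self) -> dict:
        return compute_metrics(self.tp, self.fn, self.fp, self.tn)


def compute_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Precision/recall/F1 per class plus overall accuracy.

    Division by zero yields 0 with an entry in ``flags`` rather than an
    exception.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fn + fp + tn
    if total == 0:
        raise EmptyReportError("all-zero confusion matrix")
    flags: list[str] = []

    def safe_div(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(f"{name}-undefined")
            return 0.0
        return num / den

    p_pos = safe_div(tp, tp + fp, "patient-precision")
    r_pos = safe_div(tp, tp + fn, "patient-recall")
    f1_pos = safe_div(2 * p_pos * r_pos, p_pos + r_pos, "patient-f1")
    p_neg = safe_div(tn, tn + fn, "normal-precision")
    r_neg = safe_div(tn, tn + fp, "normal-recall")
    f1_neg = safe_div(2 * p_neg * r_neg, p_neg + r_neg, "normal-f1")
    return {
        "patient": {"precision": p_pos, "recall": r_pos, "f1": f1_pos},
        "normal": {"precision": p_neg, "recall": r_neg, "f1": f1_neg},
        "accuracy": (tp + tn) / total,
        "flags": flags,
    }


class StrabismusScreener(ClassifierMixin, BaseEstimator):
    """Binary screening classifier over the 16-feature oculomotor descriptor.

    A thin sklearn-compatible wrapper: ``model_family`` selects one of the
    eight classical families with fixed default hyperparameters, and the
    decision rule calls ``patient`` when the predicted patient probability
    is at least 0.5 (ties favor sensitivity).

    Accepts a plain feature matrix in ``fit``/``predict``.  For raw
    :class:`~oculoscreen.features.SubjectSeries` inputs compose it with
    :class:`~oculoscreen.features.GazeFeaturizer` in a pipeline so the
    standard curve is learned on training folds only.
    """

    def __init__(self, model_family: str = "rf", random_state: int = 0):
        self.model_family = model_family
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.model_ = make_model(self.model_family, self.random_state)
        self.model_.fit(X, y)
        self.classes_ = np.asarray(self.model_.classes_ if hasattr(self.model_, "classes_") else np.unique(y))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        proba = self.predict_proba(X)
        classes = list(self.model_.classes_)
        if POSITIVE_LABEL in classes:
            pos = classes.index(POSITIVE_LABEL)
            is_pos = proba[:, pos] >= DECISION_THRESHOLD
            return np.where(is_pos, POSITIVE_LABEL, NEGATIVE_LABEL)
        return self.model_.classes_[np.argmax(proba, axis=1)]


def _coerce_cohort(
    cohort, labels: Sequence[str] | None
) -> tuple[pd.DataFrame | None, list[SubjectSeries] | None, np.ndarray]:
    """Accept either a feature DataFrame or a list of SubjectSeries."""
    if isinstance(cohort, pd.DataFrame):
        y = np.asarray(labels if labels is not None else cohort["label"])
        return cohort, None, y
    series = list(cohort)
    y = np.asarray(labels if labels is not None else [s.label for s in series])
    return None, series, y


def _fold_matrices(
    frame: pd.DataFrame | None,
    series: list[SubjectSeries] | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    feature_subset: Sequence[str],
):
    """Training/test design matrices for one fold.

    With raw series, the standard curve — hence F11-F16 — is rebuilt from
    the fold's training subjects only.
    """
    if frame is not None:
        X = frame[list(feature_subset)].to_numpy(dtype=float)
        return X[train_idx], X[test_idx]
    feat = GazeFeaturizer().fit([series[i] for i in train_idx], y[train_idx])
    cols = [FEATURE_NAMES.index(f) for f in feature_subset]
    X_train = feat.transform([series[i] for i in train_idx])[:, cols]
    X_test = feat.transform([series[i] for i in test_idx])[:, cols]
    return X_train, X_test


def loocv_evaluate(
    cohort,
    model_family: str = "rf",
    seed: int = 0,
    labels: Sequence[str] | None = None,
    feature_subset: Sequence[str] = FEATURE_NAMES,
) -> ClassificationReport:
    """Leave-one-out evaluation of one model family.

    ``cohort`` is either a feature DataFrame with columns F1..F16 (and
    optionally ``label``) or a sequence of :class:`SubjectSeries`; in the
    latter case standard-curve-dependent features are recomputed per fold.
    Deterministic given ``seed``.
    """
    make_model(model_family, seed)  # validate the family before any fold work
    frame, series, y = _coerce_cohort(cohort, labels)
    for lab in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if np.sum(y == lab) < 2:
            raise ConfigError(f"need >= 2 subjects of class {lab!r} for LOOCV training sets")
    bad = set(feature_subset) - set(FEATURE_NAMES)
    if bad:
        raise ConfigError(f"unknown features {sorted(bad)}")
    n = len(y)
    tp = fn = fp = tn = abstained = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        test = idx[i : i + 1]
        X_tr, X_te = _fold_matrices(frame, series, y, train, test, feature_subset)
        clf = StrabismusScreener(model_family, random_state=seed)
        try:
            clf.fit(X_tr, y[train])
            pred = clf.predict(X_te)[0]
        except ConfigError:
            raise
        except Exception:
            abstained += 1
            continue
        truth = y[i]
        if truth == POSITIVE_LABEL:
            tp += pred == POSITIVE_LABEL
            fn += pred != POSITIVE_LABEL
        else:
            tn += pred != POSITIVE_LABEL
            fp += pred == POSITIVE_LABEL
    return ClassificationReport(
        model_family=model_family,
        tp=int(tp),
        fn=int(fn),
        fp=int(fp),
        tn=int(tn),
        seed=seed,
        n_abstained=abstained,
        feature_subset=tuple(feature_subset),
    )


@dataclass
class AttributionReport:
    """Shapley-style feature attribution for one fitted model."""

    model_family: str
    weights: pd.Series  # per-feature normalized mean |attribution|, sums to 1
    values: pd.DataFrame  # per-subject signed attributions (subjects x features)

    def top_features(self, k: int = 4) -> list[str]:
        return list(self.weights.sort_values(ascending=False).index[:k])


def _shapley_sample(model, X: np.ndarray, seed: int, n_permutations: int = 64) -> np.ndarray:
    """Monte-Carlo Shapley values of the patient probability.

    For each subject and each sampled feature permutation, features are
    switched one by one from a background row (drawn from the cohort) to the
    subject's own values; the successive probability increments are unbiased
    Shapley contribution samples.  All model calls are batched.
    """
    rng = np.random.default_rng(seed)
    n, d = X.shape
    classes = list(model.classes_)
    pos = classes.index(POSITIVE_LABEL) if POSITIVE_LABEL in classes else 1

    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        bg = X[rng.integers(0, n, size=n)]
        # rows[k] has the first k features (in permutation order) from X
        batch = np.empty((d + 1, n, d))
        batch[0] = bg
        current = bg.copy()
        for k, j in enumerate(order, start=1):
            current = current.copy()
            current[:, j] = X[:, j]
            batch[k] = current
        probs = model.predict_proba(batch.reshape(-1, d))[:, pos].reshape(d + 1, n)
        inc = np.diff(probs, axis=0)  # (d, n) increments
        for k, j in enumerate(order):
            phi[:, j] += inc[k]
    return phi / n_permutations


def shap_weights(
    cohort,
    model_family: str = "rf",
    seed: int = 0,
    labels: Sequence[str] | None = None,
    n_permutations: int = 64,
) -> AttributionReport:
    """Fit on the full cohort and attribute the patient probability.

    Weights are per-feature normalized mean absolute Shapley estimates
    (nonnegative, summing to 1); the signed per-subject values are also
    returned for density plotting.
    """
    frame, series, y = _coerce_cohort(cohort, labels)
    if frame is None:
        feat = GazeFeaturizer().fit(series, y)
        X = feat.transform(series)
        ids = [s.subject_id for s in series]
    else:
        X = frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
        ids = list(frame.index)
    clf = StrabismusScreener(model_family, random_state=seed).fit(X, y)
    phi = _shapley_sample(clf, X, seed=seed, n_permutations=n_permutations)
    mean_abs = np.abs(phi).mean(axis=0)
    total = mean_abs.sum()
    weights = mean_abs / total if total > 0 else np.full(len(FEATURE_NAMES), 1 / len(FEATURE_NAMES))
    return AttributionReport(
        model_family=model_family,
        weights=pd.Series(weights, index=FEATURE_NAMES),
        values=pd.DataFrame(phi, columns=FEATURE_NAMES, index=ids),
    )


def ablation_study(
    cohort,
    feature_subsets: Sequence[Sequence[str]],
    model_family: str = "rf",
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> list[ClassificationReport]:
    """Re-run LOOCV with each listed feature set *dropped*.

    Every subset must be a proper subset of F1..F16 (dropping everything is
    a configuration error).
    """
    reports = []
    for drop in feature_subsets:
        drop = set(drop)
        bad = drop - set(FEATURE_NAMES)
        if bad:
            raise ConfigError(f"unknown features {sorted(bad)}")
        remaining = [f for f in FEATURE_NAMES if f not in drop]
        if not remaining:
            raise ConfigError("cannot drop all 16 features")
        reports.append(
            loocv_evaluate(cohort, model_family, seed, labels, feature_subset=remaining)
        )
    return reports


def model_comparison(
    cohort, seed: int = 0, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """LOOCV all eight families; one row per family.

    Columns: patient precision/recall/F1, overall accuracy, abstentions.
    Per-family failures are recorded as NaN rows; the table is still emitted.
    """
    rows = []
    for family in MODEL_FAMILIES:
        try:
            rep = loocv_evaluate(cohort, family, seed, labels)
            m = rep.metrics()
            rows.append(
                {
                    "model": family,
                    "patient_precision": m["patient"]["precision"],
                    "patient_recall": m["patient"]["recall"],
                    "patient_f1": m["patient"]["f1"],
                    "accuracy": m["accuracy"],
                    "n_abstained": rep.n_abstained,
                }
            )
        except ConfigError:
            raise
        except Exception as exc:  # keep the table even if one family fails
            rows.append({"model": family, "error": str(exc)})
    return pd.DataFrame(rows).set_index("model")
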