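"""Annotation aggregation, SMOTE balancing and the 5-fold
cross-validated four-classifier harness.

The four classifiers (MLP, random forest, SVM, bagging) are standard
models delegated to scikit-learn behind one configuration block; this
module owns the harness around them: majority-vote label aggregation
with a severity tie-break, categorical feature encoding, in-fold SMOTE
applied to the training portion only, the stratified 5-fold loop, and
the per-fold metric set

    M = {Accuracy, TPR, FPR, Precision, Recall, F-Measure, ROC,
         kappa, RMSE}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import (
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS
from .synth import majority_vote

__all__ = [
    "aggregate_annotations",
    "FeatureEncoder",
    "SMOTEResampler",
    "CTGClassifier",
    "MODEL_NAMES",
    "LabelledDataset",
    "CVResult",
    "run_cv",
    "fold_metric_correlation",
    "METRIC_NAMES",
]

MODEL_NAMES = ("mlp", "rf", "svm", "bagging")
METRIC_NAMES = (
    "accuracy", "tpr", "fpr", "precision", "recall",
    "f_measure", "roc", "kappa", "rmse",
)

#: hyperparameters of the four standard classifiers, in one block.
#: The MLP uses three sigmoid hidden layers; the rest run at common
#: library defaults sized for a few hundred rows.
MODEL_CONFIG: dict[str, dict] = {
    "mlp": dict(hidden_layer_sizes=(32, 32, 32), activation="logistic",
                max_iter=1500, tol=1e-4),
    "rf": dict(n_estimators=200),
    "svm": dict(kernel="rbf", C=10.0, gamma="scale", probability=True),
    "bagging": dict(n_estimators=50),
}


def aggregate_annotations(rater_labels: Sequence[int]) -> int:
    """Final class of one record from its six clinician annotations.

    Majority vote; ties break toward the more severe class (a record
    split between Suspicious and Pathological is treated as
    Pathological).
    """
    if len(rater_labels) != 6:
        raise ValueError(f"expected 6 rater labels, got {len(rater_labels)}")
    if any(l not in (1, 2, 3) for l in rater_labels):
        raise ValueError("rater labels must be in {1, 2, 3}")
    return majority_vote(rater_labels)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

_VARIABILITY_ORDER = {"Absent": 0, "Minimal": 1, "Moderate": 2, "Marked": 3,
                      "Undetermined": -1}
_ONE_HOT = {
    "baseline_type": ("Normal", "Bradycardia", "Tachycardia", "Undetermined"),
    "shr": ("Present", "Absent", "Undetermined"),
    "stage": ("normal", "stage1", "stage2"),
}


class FeatureEncoder(BaseEstimator, TransformerMixin):
    """Encode the 11-feature table numerically for the classifiers.

    Ordered categories (variability type) are ordinal-coded; unordered
    ones (baseline type, sinusoidal pattern, stage) are one-hot. An
    Undetermined numeric baseline or variability is carried as value 0
    plus an explicit determined/undetermined indicator column — it is
    never silently imputed.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureEncoder":
        self.columns_ = self._encode(X).columns.tolist()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        out = self._encode(X)
        return out.reindex(columns=self.columns_, fill_value=0.0)

    @staticmethod
    def _encode(X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        out = pd.DataFrame(index=X.index)
        base = pd.to_numeric(X["baseline"], errors="coerce")
        out["baseline"] = base.fillna(0.0)
        out["baseline_determined"] = base.notna().astype(float)
        var = pd.to_numeric(X["variability"], errors="coerce")
        out["variability"] = var.fillna(0.0)
        out["variability_determined"] = var.notna().astype(float)
        out["variability_type"] = (
            X["variability_type"].map(_VARIABILITY_ORDER).astype(float)
        )
        out["acceleration_present"] = X["acceleration_present"].astype(float)
        for c in ("n_accelerations", "n_early", "n_late", "n_variable"):
            out[c] = X[c].astype(float)
        for col, levels in _ONE_HOT.items():
            for level in levels:
                out[f"{col}_{level}"] = (X[col] == level).astype(float)
        return out


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


class SMOTEResampler(BaseEstimator):
    """Synthetic minority oversampling to class parity.

    Each synthetic row interpolates between a minority-class sample
    and one of its ``k_neighbors`` nearest minority-class neighbours
    (Euclidean), at a uniform random point of the segment. Classes are
    brought up to the majority count. When a minority class has fewer
    than ``k_neighbors + 1`` members, k is reduced with a warning.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (X_res, y_res, synthetic) with a boolean flag per row."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        target = counts.max()
        new_X, new_y = [X], [y]
        synthetic = [np.zeros(len(y), dtype=bool)]
        for cls, count in zip(classes, counts):
            need = target - count
            if need == 0:
                continue
            Xc = X[y == cls]
            if len(Xc) == 1:
                warnings.warn(
                    f"class {cls} has a single sample; SMOTE duplicates it"
                )
                rows = np.repeat(Xc, need, axis=0)
            else:
                k = self.k_neighbors
                if len(Xc) - 1 < k:
                    k = len(Xc) - 1
                    warnings.warn(
                        f"class {cls} has {len(Xc)} samples; reducing "
                        f"k_neighbors to {k}"
                    )
                d = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=2)
                np.fill_diagonal(d, np.inf)
                nn = np.argsort(d, axis=1)[:, :k]
                base_idx = rng.integers(0, len(Xc), size=need)
                nb_idx = nn[base_idx, rng.integers(0, k, size=need)]
                t = rng.uniform(0, 1, size=need)[:, None]
                rows = Xc[base_idx] + t * (Xc[nb_idx] - Xc[base_idx])
            new_X.append(rows)
            new_y.append(np.full(need, cls, dtype=y.dtype))
            synthetic.append(np.ones(need, dtype=bool))
        return (
            np.vstack(new_X),
            np.concatenate(new_y),
            np.concatenate(synthetic),
        )


@dataclass
class LabelledDataset:
    """Numeric feature rows with labels and row provenance.

    ``provenance`` distinguishes real/synthetic-generator rows from
    SMOTE-interpolated ones; SMOTE rows may only ever appear in
    training folds.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("rows and labels are not aligned")
        if self.provenance is None:
            self.provenance = np.array(["real"] * len(self.y), dtype=object)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def _base_model(model: str, random_state: int | None) -> BaseEstimator:
    cfg = MODEL_CONFIG[model]
    if model == "mlp":
        return MLPClassifier(random_state=random_state, **cfg)
    if model == "rf":
        return RandomForestClassifier(random_state=random_state, **cfg)
    if model == "svm":
        return SVC(random_state=random_state, **cfg)
    return BaggingClassifier(random_state=random_state, **cfg)


class CTGClassifier(BaseEstimator, ClassifierMixin):
    """One of the four standard CTG classifiers behind a common front.

    Parameters
    ----------
    model : {"mlp", "rf", "svm", "bagging"}
        Which classifier to fit. The MLP uses three hidden layers with
        sigmoid activation; all hyperparameters live in
        :data:`MODEL_CONFIG`.
    random_state : int or None
        Fixes model initialisation (and therefore predictions).

    Features are standardised internally, so the estimator composes
    directly with raw encoded feature tables.
    """

    def __init__(self, model: str = "rf", random_state: int | None = None):
        self.model = model
        self.random_state = random_state

    def fit(self, X, y):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", _base_model(self.model, self.random_state)),
            ]
        )
        with warnings.catch_warnings():
            # sklearn >= 1.9 deprecates SVC(probability=True); the Platt
            # scaling it performs is exactly what the harness needs
            warnings.filterwarnings("ignore", category=FutureWarning)
            self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Outcome of one stratified k-fold run for one classifier."""

    model: str
    fold_metrics: pd.DataFrame          # k rows x 9 metrics
    actual: np.ndarray                  # pooled out-of-fold truth
    predicted: np.ndarray               # pooled out-of-fold predictions
    proba: np.ndarray                   # pooled out-of-fold class scores
    fold_of_row: np.ndarray             # fold index of each pooled row
    classes: np.ndarray

    @property
    def pooled_accuracy(self) -> float:
        return float(np.mean(self.actual == self.predicted))


def _fold_metrics(y_true, y_pred, proba, classes) -> dict[str, float]:
    labels = list(classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # weighted one-vs-rest FPR
        fprs, weights = [], []
        for c in labels:
            pos = y_true == c
            neg = ~pos
            fp = np.count_nonzero((y_pred == c) & neg)
            fprs.append(fp / max(np.count_nonzero(neg), 1))
            weights.append(np.count_nonzero(pos))
        fpr = float(np.average(fprs, weights=weights))
        try:
            roc = float(
                roc_auc_score(y_true, proba, multi_class="ovr",
                              average="weighted", labels=labels)
            )
        except ValueError:
            roc = float("nan")
        return {
            "accuracy": float(np.mean(y_true == y_pred)),
            "tpr": float(recall_score(y_true, y_pred, average="weighted",
                                      zero_division=0)),
            "fpr": fpr,
            "precision": float(precision_score(y_true, y_pred,
                                               average="weighted",
                                               zero_division=0)),
            "recall": float(recall_score(y_true, y_pred, average="weighted",
                                         zero_division=0)),
            "f_measure": float(f1_score(y_true, y_pred, average="weighted",
                                        zero_division=0)),
            "roc": roc,
            "kappa": float(cohen_kappa_score(y_true, y_pred)),
            "rmse": float(np.sqrt(np.mean((np.asarray(y_true, float)
                                           - np.asarray(y_pred, float)) ** 2))),
        }


def run_cv(
    data: LabelledDataset,
    model: str,
    k: int = 5,
    seed: int | None = 0,
    smote: bool = False,
    k_neighbors: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier.

    Each fold optionally applies SMOTE to its training portion only
    (test folds always contain original rows — asserted, not assumed),
    fits the model, and scores the held-out fold with the full metric
    set. Folds and model initialisation are fixed by ``seed``.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}")
    X, y = data.X, data.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratification failure: class {classes[np.argmin(counts)]} has "
            f"{counts.min()} samples for k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    actual = np.empty(len(y), dtype=y.dtype)
    predicted = np.empty(len(y), dtype=y.dtype)
    proba = np.zeros((len(y), len(classes)))
    fold_of_row = np.empty(len(y), dtype=int)
    rows = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[train], y[train]
        if smote:
            X_tr, y_tr, synth = SMOTEResampler(
                k_neighbors=k_neighbors,
                random_state=None if seed is None else seed + fold,
            ).fit_resample(X_tr, y_tr)
        # leakage guard: the test rows come straight from the original data
        assert np.all(data.provenance[test] != "smote"), "SMOTE row in test fold"
        clf = CTGClassifier(
            model=model, random_state=None if seed is None else seed + fold
        ).fit(X_tr, y_tr)
        y_hat = clf.predict(X[test])
        p = clf.predict_proba(X[test])
        # align probability columns to the global class order
        col = {c: i for i, c in enumerate(clf.classes_)}
        p_full = np.zeros((len(test), len(classes)))
        for j, c in enumerate(classes):
            if c in col:
                p_full[:, j] = p[:, col[c]]
        actual[test] = y[test]
        predicted[test] = y_hat
        proba[test] = p_full
        fold_of_row[test] = fold
        rows.append(_fold_metrics(y[test], y_hat, p_full, classes))
    return CVResult(
        model=model,
        fold_metrics=pd.DataFrame(rows, columns=list(METRIC_NAMES)),
        actual=actual,
        predicted=predicted,
        proba=proba,
        fold_of_row=fold_of_row,
        classes=classes,
    )


def fold_metric_correlation(
    results: dict[str, CVResult]
) -> list[pd.DataFrame]:
    """Per-fold Pearson correlation between the models' metric vectors.

    For every fold, each model contributes its 9-value metric vector M;
    the 4x4 (or m x m) correlation matrix of those vectors is returned,
    one DataFrame per fold. A zero-variance metric vector yields NaN
    against every other model, reported as such.
    """
    names = list(results)
    ks = {len(r.fold_metrics) for r in results.values()}
    if len(ks) != 1:
        raise ValueError("all models must use the same folds")
    k = ks.pop()
    out = []
    for fold in range(k):
        mat = pd.DataFrame(index=names, columns=names, dtype=float)
        vecs = {
            m: results[m].fold_metrics.iloc[fold].to_numpy(dtype=float)
            for m in names
        }
        for a in names:
            for b in names:
                va, vb = vecs[a], vecs[b]
                ok = np.isfinite(va) & np.isfinite(vb)
                va, vb = va[ok], vb[ok]
                if a == b:
                    mat.loc[a, b] = 1.0
                elif va.std() == 0 or vb.std() == 0:
                    mat.loc[a, b] = np.nan
                else:
                    mat.loc[a, b] = float(np.corrcoef(va, vb)[0, 1])
        out.append(mat)
    return out
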