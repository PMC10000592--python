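"""Evaluation battery: model metrics, combined measures, contingency
chi-squared, Bland–Altman agreement, KMO/Bartlett adequacy, scree
eigenvalues and multiclass AUC.

Everything operates on the 3-class confusion matrix (actual vs
predicted over {Normal=1, Suspicious=2, Pathological=3}) or on the
raw label sequences. Display rounding, where used, is half-away-from-
zero to 3 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix3",
    "MetricReport",
    "AgreementReport",
    "confusion",
    "sequences_from_confusion",
    "model_metrics",
    "combined_metrics",
    "chi2_independence",
    "chi2_critical_value",
    "bland_altman",
    "kmo_bartlett",
    "scree_eigenvalues",
    "multiclass_auc",
    "round3",
]

CLASSES = (1, 2, 3)


def round3(x: float) -> float:
    """Half-away-from-zero rounding to 3 decimals (table display)."""
    return float(np.sign(x) * np.floor(abs(x) * 1000 + 0.5) / 1000)


@dataclass
class ConfusionMatrix3:
    """3x3 actual-vs-predicted counts over {1, 2, 3}."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion(actual, predicted) -> ConfusionMatrix3:
    """Tally the 3x3 contingency table of actual vs predicted classes."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted differ in length")
    if len(actual) == 0:
        raise ValueError("empty input")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        bad = set(np.unique(arr)) - set(CLASSES)
        if bad:
            raise ValueError(f"{name} contains labels outside {{1,2,3}}: {bad}")
    counts = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, predicted):
        counts[a - 1, p - 1] += 1
    return ConfusionMatrix3(counts)


def sequences_from_confusion(cm: ConfusionMatrix3) -> tuple[np.ndarray, np.ndarray]:
    """Any (actual, predicted) pair of sequences realizing the counts."""
    actual, predicted = [], []
    for a in CLASSES:
        for p in CLASSES:
            c = cm.counts[a - 1, p - 1]
            actual.extend([a] * c)
            predicted.extend([p] * c)
    return np.asarray(actual), np.asarray(predicted)


# ---------------------------------------------------------------------------
# model + combined metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Model metrics (first four) and combined measures (last six)."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    g_mean: float | None = None
    discriminant_power: float | None = None
    balanced_accuracy: float | None = None
    mcc: float | None = None
    kappa: float | None = None
    youden: float | None = None


def _one_vs_rest(cm: ConfusionMatrix3):
    """(sensitivity, specificity, precision, support) per class."""
    C = cm.counts.astype(float)
    n = C.sum()
    sens, spec, prec, support = [], [], [], []
    for i in range(3):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        support.append(C[i].sum())
        sens.append(tp / (tp + fn) if tp + fn > 0 else np.nan)
        spec.append(tn / (tn + fp) if tn + fp > 0 else np.nan)
        prec.append(tp / (tp + fp) if tp + fp > 0 else np.nan)
    return map(np.asarray, (sens, spec, prec, support))


def _average(values: np.ndarray, support: np.ndarray, mode: str) -> float:
    ok = np.isfinite(values)
    if not ok.all():
        warnings.warn("class with empty margin excluded from averaging")
    values, support = values[ok], support[ok]
    if mode == "macro":
        return float(values.mean())
    return float(np.average(values, weights=support))


def model_metrics(cm: ConfusionMatrix3, average: str = "weighted") -> MetricReport:
    """Accuracy and one-vs-rest sensitivity/specificity/precision.

    ``average`` is ``weighted`` (support-weighted, the default) or
    ``macro``. Under weighted averaging sensitivity equals accuracy.
    """
    if average not in ("weighted", "macro"):
        raise ValueError("average must be 'weighted' or 'macro'")
    sens, spec, prec, support = _one_vs_rest(cm)
    return MetricReport(
        accuracy=float(np.trace(cm.counts) / cm.n),
        sensitivity=_average(sens, support, average),
        specificity=_average(spec, support, average),
        precision=_average(prec, support, average),
    )


def _kappa(cm: ConfusionMatrix3) -> float:
    C = cm.counts.astype(float)
    n = C.sum()
    po = np.trace(C) / n
    pe = float((C.sum(0) * C.sum(1)).sum()) / n**2
    return (po - pe) / (1 - pe)


def _mcc(cm: ConfusionMatrix3) -> float:
    """Multiclass Matthews correlation (Gorodkin's R_k) from the matrix."""
    C = cm.counts.astype(float)
    n = C.sum()
    t = C.sum(axis=1)  # actual totals
    p = C.sum(axis=0)  # predicted totals
    cov_tp = np.trace(C) * n - t @ p
    cov_pp = n**2 - p @ p
    cov_tt = n**2 - t @ t
    denom = np.sqrt(cov_pp * cov_tt)
    return float(cov_tp / denom) if denom > 0 else 0.0


def combined_metrics(
    cm: ConfusionMatrix3,
    sensitivity: float | None = None,
    specificity: float | None = None,
) -> MetricReport:
    """Combined measures built from sensitivity and specificity.

    g_mean = sqrt(sens * spec);
    DP = (sqrt(3)/pi) * [ln(sens/(1-spec)) + ln(spec/(1-sens))];
    balanced accuracy = (macro sensitivity + macro specificity)/2;
    multiclass MCC and Cohen's kappa from the confusion matrix;
    Youden's J = sens + spec - 1.

    ``sensitivity``/``specificity`` default to the support-weighted
    one-vs-rest values of the matrix. DP is infinite when either rate
    touches 0 or 1 (reported as +/-inf, never silently clipped).
    """
    mm = model_metrics(cm, average="weighted")
    sens = mm.sensitivity if sensitivity is None else sensitivity
    spec = mm.specificity if specificity is None else specificity
    if 0 < sens < 1 and 0 < spec < 1:
        dp = (np.sqrt(3) / np.pi) * (
            np.log(sens / (1 - spec)) + np.log(spec / (1 - sens))
        )
    else:
        dp = float("inf")
    macro = model_metrics(cm, average="macro")
    return MetricReport(
        g_mean=float(np.sqrt(sens * spec)),
        discriminant_power=float(dp),
        balanced_accuracy=(macro.sensitivity + macro.specificity) / 2,
        mcc=_mcc(cm),
        kappa=_kappa(cm),
        youden=sens + spec - 1,
    )


# ---------------------------------------------------------------------------
# chi-squared independence + Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Chi-squared and Bland–Altman agreement for one classifier."""

    chi2: float | None = None
    df: int | None = None
    p: float | None = None
    critical_value: float | None = None
    reject_independence: bool | None = None
    ba_mean_diff: float | None = None
    ba_mean_ci: tuple[float, float] | None = None
    ba_loa_upper: float | None = None
    ba_loa_upper_ci: tuple[float, float] | None = None
    ba_loa_lower: float | None = None
    ba_loa_lower_ci: tuple[float, float] | None = None
    ba_slope: float | None = None
    ba_slope_ci: tuple[float, float] | None = None
    ba_intercept: float | None = None
    ba_intercept_ci: tuple[float, float] | None = None


def chi2_critical_value(alpha: float = 0.05, df: int = 4) -> float:
    return float(stats.chi2.ppf(1 - alpha, df))


def chi2_independence(cm: ConfusionMatrix3, alpha: float = 0.05) -> AgreementReport:
    """Pearson chi-squared test of independence on the 3x3 table.

    Expected counts are outer(row margins, column margins)/n; df = 4.
    The null (actual and predicted classifications independent) is
    rejected when the statistic exceeds the critical value at alpha.
    """
    C = cm.counts.astype(float)
    rows, cols = cm.row_totals().astype(float), cm.col_totals().astype(float)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: expected counts undefined")
    expected = np.outer(rows, cols) / cm.n
    chi2 = float(((C - expected) ** 2 / expected).sum())
    df = (3 - 1) * (3 - 1)
    crit = chi2_critical_value(alpha, df)
    return AgreementReport(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        critical_value=crit,
        reject_independence=chi2 > crit,
    )


def bland_altman(
    actual, predicted, sd_ddof: int = 0, alpha: float = 0.05
) -> AgreementReport:
    """Bland–Altman agreement between annotation and prediction.

    Differences are d = actual − predicted. The bias is mean(d); the
    95% limits of agreement are mean ± 1.96·sd(d) (population sd by
    default, ``sd_ddof=1`` for the sample convention). Confidence
    intervals use the large-sample normal forms: se(mean) = sd/√n and
    se(LoA) = sd·√(3/n). Slope and intercept come from least squares
    of d on the pairwise means (a proportional-bias check).
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(actual)
    if n != len(predicted):
        raise ValueError("actual and predicted differ in length")
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    d = actual - predicted
    mean = (actual + predicted) / 2
    md = float(d.mean())
    sd = float(d.std(ddof=sd_ddof))
    z = float(stats.norm.ppf(1 - alpha / 2))
    loa_up, loa_lo = md + z * sd, md - z * sd
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    # proportional-bias regression of difference on mean
    import statsmodels.api as sm

    X = sm.add_constant(mean)
    fit = sm.OLS(d, X).fit()
    ci = fit.conf_int(alpha)
    return AgreementReport(
        ba_mean_diff=md,
        ba_mean_ci=(md - z * se_mean, md + z * se_mean),
        ba_loa_upper=loa_up,
        ba_loa_upper_ci=(loa_up - z * se_loa, loa_up + z * se_loa),
        ba_loa_lower=loa_lo,
        ba_loa_lower_ci=(loa_lo - z * se_loa, loa_lo + z * se_loa),
        ba_intercept=float(fit.params[0]),
        ba_intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        ba_slope=float(fit.params[1]),
        ba_slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


# ---------------------------------------------------------------------------
# adequacy diagnostics
# ---------------------------------------------------------------------------


def kmo_bartlett(features: np.ndarray) -> tuple[float, float, int, float]:
    """KMO sampling adequacy and Bartlett's sphericity test.

    KMO compares observed correlations r_ij against anti-image partial
    correlations a_ij (from the inverse correlation matrix):
    KMO = sum r^2 / (sum r^2 + sum a^2) over off-diagonal pairs.
    Bartlett: chi2 = -(n-1-(2p+5)/6) * ln det(R), df = p(p-1)/2.

    Returns (kmo, bartlett_chi2, df, p_value).
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or np.linalg.cond(R) > 1e10:
        raise ValueError("correlation matrix is singular (duplicated or "
                         "constant column?)")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    a2 = float((partial[off] ** 2).sum())
    kmo = r2 / (r2 + a2)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return kmo, float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def scree_eigenvalues(features: np.ndarray) -> np.ndarray:
    """Eigenvalues of the feature correlation matrix, descending.

    Their sum equals the number of columns; the inflexion point of the
    scree curve suggests how many factors carry signal.
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    R = np.corrcoef(X, rowvar=False)
    if not np.isfinite(R).all():
        raise ValueError("correlation matrix is undefined (constant column?)")
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def multiclass_auc(scores: np.ndarray, actual) -> tuple[dict[int, float], float]:
    """One-vs-rest trapezoidal AUC per class plus the macro mean.

    ``scores`` has one column per class in ascending class order. Ties
    are handled by the midpoint convention. A class absent from
    ``actual`` has undefined AUC, reported as NaN and excluded from
    the macro mean.
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual, dtype=int)
    per_class: dict[int, float] = {}
    for j, c in enumerate(CLASSES):
        pos = actual == c
        if pos.all() or not pos.any():
            per_class[c] = float("nan")
            continue
        per_class[c] = float(roc_auc_score(pos, scores[:, j]))
    vals = [v for v in per_class.values() if np.isfinite(v)]
    macro = float(np.mean(vals)) if vals else float("nan")
    return per_class, macro
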