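"""Threshold derivation and validation for sedentary-vs-activity tasks.

For each discrimination dataset (metric values in mg, binary labels) this
module fits a univariate binary logistic regression, traces the ROC curve
of the rule ``value >= threshold -> activity``, picks the optimal threshold
by Youden's J (J = sensitivity + specificity - 1; ties broken by higher
sensitivity, then lower threshold), summarises discrimination by the AUROC
(Mann-Whitney pair-counting estimator, ties half-credited) with a DeLong
95% confidence interval, and validates by leave-one-out cross-validation:
each held-out unit's predicted probability is recorded and the out-of-fold
predictions are pooled into a single LOOCV AUROC.

Logistic fits use iteratively reweighted least squares.  Perfect separation
(a diverging slope or non-convergence) triggers a ridge-stabilised refit
(penalty 1e-6 on the slope) reported with ``converged=False`` and
``fallback=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .labeling import DISCRIMINATIONS, DiscriminationDataset, build_discrimination

__all__ = [
    "LogisticFit",
    "AurocResult",
    "TTestResult",
    "ThresholdReport",
    "fit_logistic",
    "roc_curve",
    "optimal_threshold",
    "auroc",
    "loocv_auroc",
    "compare_brands",
    "derive_threshold_report",
    "run_threshold_battery",
]

MAX_IRLS_ITER = 100
GRAD_TOL = 1e-8
SLOPE_DIVERGENCE = 1e4  # per mg; beyond this the fit is treated as separated
RIDGE_FALLBACK = 1e-6
Z_95 = 1.959963984540054


@dataclass
class LogisticFit:
    """Univariate logistic model logit P(activity) = intercept + slope * value."""

    intercept: float
    slope: float
    converged: bool
    n_iter: int
    log_likelihood: float
    fallback: bool = False

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(values, dtype=float)
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _log_likelihood(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _irls(x: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, bool, int]:
    """Newton/IRLS for the two-parameter logistic; ridge penalises the slope only."""
    pbar = y.mean()
    beta = np.array([np.log(pbar / (1 - pbar)), 0.0])
    X = np.column_stack([np.ones_like(x), x])
    penalty = np.diag([0.0, ridge])
    converged = False
    it = 0
    for it in range(1, MAX_IRLS_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = X.T @ (y - p) - penalty @ beta
        if np.linalg.norm(grad) < GRAD_TOL:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + penalty
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if not np.all(np.isfinite(beta)) or abs(beta[1]) > SLOPE_DIVERGENCE:
            converged = False
            break
    return beta, converged, it


def fit_logistic(ds: DiscriminationDataset | tuple[np.ndarray, np.ndarray]) -> LogisticFit:
    """Maximum-likelihood univariate logistic fit with separation fallback."""
    if isinstance(ds, DiscriminationDataset):
        x, y = ds.values, ds.labels
    else:
        x = np.asarray(ds[0], dtype=float)
        y = np.asarray(ds[1], dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("logistic fit requires both classes present")

    beta, converged, n_iter = _irls(x, y, ridge=0.0)
    fallback = False
    # a saturated likelihood (ll ~ 0) means the MLE lies at infinity even if
    # the gradient already vanished numerically: perfect separation
    p0 = 1.0 / (1.0 + np.exp(-np.clip(beta[0] + beta[1] * x, -700, 700)))
    saturated = _log_likelihood(p0, y) > -1e-6
    if not converged or saturated or abs(beta[1]) > SLOPE_DIVERGENCE:
        beta, _, n_iter2 = _irls(x, y, ridge=RIDGE_FALLBACK)
        n_iter += n_iter2
        converged = False
        fallback = True
    p = 1.0 / (1.0 + np.exp(-np.clip(beta[0] + beta[1] * x, -700, 700)))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        converged=converged,
        n_iter=n_iter,
        log_likelihood=_log_likelihood(p, y),
        fallback=fallback,
    )


def _split_scores(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("ROC/AUROC require both classes present")
    return pos, neg


def roc_curve(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC points for the rule ``score >= threshold -> positive``.

    One point per distinct score plus the two degenerate endpoints
    (threshold +inf: sens 0 / spec 1; threshold -inf: sens 1 / spec 0);
    consecutive duplicate (sensitivity, specificity) pairs are collapsed.
    """
    pos, neg = _split_scores(values, labels)
    thresholds = np.concatenate(([np.inf], np.unique(values)[::-1], [-np.inf]))
    rows = []
    prev = None
    for thr in thresholds:
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        if (sens, spec) != prev:
            rows.append({"threshold": thr, "sensitivity": sens, "specificity": spec})
            prev = (sens, spec)
    return pd.DataFrame(rows)


def optimal_threshold(
    roc: pd.DataFrame, criterion: str = "youden"
) -> tuple[float, float, float]:
    """Pick the optimal observed threshold from a ROC table.

    Youden's J is maximised over finite thresholds; ties are broken by
    higher sensitivity, then lower threshold.  A degenerate ROC (no finite
    point, i.e. a single distinct score) raises.
    """
    if criterion != "youden":
        raise ValidationError(f"unknown criterion {criterion!r}")
    finite = roc[np.isfinite(roc["threshold"])]
    if len(finite) == 0:
        raise ValidationError("degenerate ROC: no finite threshold to choose")
    j = finite["sensitivity"] + finite["specificity"] - 1.0
    best_j = j.max()
    if len(finite) == 1 and best_j <= 0:
        raise ValidationError("degenerate ROC: scores take a single value")
    if best_j <= 0:
        warnings.warn(
            "scores do not discriminate in the expected direction (max J <= 0)",
            stacklevel=2,
        )
    ties = finite[j == best_j]
    ties = ties[ties["sensitivity"] == ties["sensitivity"].max()]
    row = ties.loc[ties["threshold"].idxmin()]
    return float(row["threshold"]), float(row["sensitivity"]), float(row["specificity"])


@dataclass
class AurocResult:
    auroc: float
    ci: tuple[float, float]
    variance: float
    n_pos: int
    n_neg: int


def auroc(values: np.ndarray, labels: np.ndarray) -> AurocResult:
    """Mann-Whitney AUROC (ties half-credited) with a DeLong 95% CI.

    The DeLong variance is built from the placement components
    ``V10_i = mean_j psi(pos_i, neg_j)`` and ``V01_j = mean_i psi``, with
    ``psi`` = 1, 0.5, 0 for pos > / = / < neg; the normal-approximation CI
    is clamped to [0, 1].
    """
    pos, neg = _split_scores(values, labels)
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = Z_95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return AurocResult(auroc=auc, ci=ci, variance=var, n_pos=m, n_neg=n)


def loocv_auroc(
    ds: DiscriminationDataset | tuple[np.ndarray, np.ndarray],
    unit: str = "observation",
) -> AurocResult:
    """Pooled leave-one-out cross-validated AUROC.

    For each held-out unit a logistic model is refitted on the remaining
    observations and the held-out predicted probabilities recorded; the
    pooled out-of-fold predictions are scored by :func:`auroc`.  With
    ``unit="observation"`` each fold holds out one observation (training on
    n-1); ``unit="participant"`` holds out all of a participant's
    observations at once (the subject-independent variant).  A training
    fold that loses one class entirely falls back to predicting the fold's
    class prevalence.
    """
    if isinstance(ds, DiscriminationDataset):
        x, y = ds.values, ds.labels
        participants = ds.observations["participant_id"].to_numpy()
    else:
        x = np.asarray(ds[0], dtype=float)
        y = np.asarray(ds[1], dtype=int)
        participants = np.arange(x.size)
    if unit not in ("observation", "participant"):
        raise ValidationError(f"unknown LOOCV unit {unit!r}")
    n = x.size
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 observations")

    if unit == "observation":
        folds = [np.array([i]) for i in range(n)]
    else:
        folds = [np.flatnonzero(participants == p) for p in pd.unique(participants)]
        if len(folds) < 3:
            raise ValidationError("participant-level LOOCV needs >= 3 participants")

    preds = np.empty(n)
    n_prevalence_folds = 0
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        y_tr = y[mask]
        if y_tr.min() == y_tr.max():  # single-class training fold
            preds[held] = y_tr.mean()
            n_prevalence_folds += 1
            continue
        fit = fit_logistic((x[mask], y_tr))
        preds[held] = fit.predict_proba(x[held])
    if n_prevalence_folds:
        warnings.warn(
            f"{n_prevalence_folds} LOOCV training fold(s) contained a single "
            "class; prevalence prediction used",
            stacklevel=2,
        )
    return auroc(preds, y)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    flagged: bool = False


def compare_brands(
    values_a: np.ndarray, values_b: np.ndarray, variant: str = "student"
) -> TTestResult:
    """Two-sample unpaired t-test on per-participant means (two-sided).

    ``variant="student"`` (default) pools variances; ``"welch"`` does not.
    Two zero-variance groups with equal means return t=0, p=1, flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if variant == "student" else float("nan")
        return TTestResult(t=0.0, df=df, p=1.0, flagged=True)
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass
class ThresholdReport:
    """One metric x brand x placement x discrimination summary row."""

    metric: str
    brand: str
    placement: str
    discrimination: str
    threshold_mg: float
    sensitivity: float
    specificity: float
    auroc: float
    auroc_ci: tuple[float, float]
    loocv_auroc: float
    loocv_auroc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    logistic_slope: float
    logistic_intercept: float
    converged: bool

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "brand": self.brand,
            "placement": self.placement,
            "discrimination": self.discrimination,
            "threshold_mg": self.threshold_mg,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auroc": self.auroc,
            "auroc_lo": self.auroc_ci[0],
            "auroc_hi": self.auroc_ci[1],
            "loocv_auroc": self.loocv_auroc,
            "loocv_lo": self.loocv_auroc_ci[0],
            "loocv_hi": self.loocv_auroc_ci[1],
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "logistic_slope": self.logistic_slope,
            "logistic_intercept": self.logistic_intercept,
            "converged": self.converged,
        }


def derive_threshold_report(
    ds: DiscriminationDataset,
    *,
    brand: str = "",
    placement: str = "",
    loocv_unit: str = "observation",
) -> ThresholdReport:
    """Full threshold analysis for one discrimination dataset."""
    fit = fit_logistic(ds)
    apparent = auroc(ds.values, ds.labels)
    # rank invariance: a positive-slope logistic transform is monotone, so
    # the AUROC of predicted probabilities must equal the AUROC of values
    if fit.slope > 0:
        auc_probs = auroc(fit.predict_proba(ds.values), ds.labels).auroc
        assert abs(auc_probs - apparent.auroc) < 1e-12, (
            "rank invariance violated between raw values and predicted "
            "probabilities"
        )
    roc = roc_curve(ds.values, ds.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anti-discriminating strata still reported
        thr, sens, spec = optimal_threshold(roc)
        loocv = loocv_auroc(ds, unit=loocv_unit)
    return ThresholdReport(
        metric=ds.metric,
        brand=brand,
        placement=placement,
        discrimination=ds.discrimination_id,
        threshold_mg=thr,
        sensitivity=sens,
        specificity=spec,
        auroc=apparent.auroc,
        auroc_ci=apparent.ci,
        loocv_auroc=loocv.auroc,
        loocv_auroc_ci=loocv.ci,
        n_pos=apparent.n_pos,
        n_neg=apparent.n_neg,
        logistic_slope=fit.slope,
        logistic_intercept=fit.intercept,
        converged=fit.converged,
    )


def run_threshold_battery(
    labeled: pd.DataFrame,
    metrics: tuple[str, ...] = ("enmo", "mad"),
    discriminations: tuple[str, ...] = tuple(DISCRIMINATIONS),
    granularity: str = "participant_activity_mean",
    loocv_unit: str = "observation",
) -> pd.DataFrame:
    """Threshold reports for every metric x brand x placement x discrimination.

    Strata are taken from the ``brand``/``placement`` columns of the
    labelled epoch table; an empty or single-class stratum is skipped with
    a warning rather than failing the whole battery.
    """
    rows = []
    for (brand, placement), stratum in labeled.groupby(
        ["brand", "placement"], observed=True, sort=True
    ):
        for metric in metrics:
            for disc in discriminations:
                try:
                    ds = build_discrimination(stratum, metric, disc, granularity)
                except ValidationError as exc:
                    warnings.warn(
                        f"skipping {metric}/{brand}/{placement}/{disc}: {exc}",
                        stacklevel=2,
                    )
                    continue
                report = derive_threshold_report(
                    ds, brand=brand, placement=placement, loocv_unit=loocv_unit
                )
                rows.append(report.to_row())
    return pd.DataFrame(rows)
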