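"""Figures of merit, binomial confidence intervals, ROC curves, and
influence-function confidence intervals for cross-validated AUC.

Per-repetition figures of merit are computed from each repetition's summed
confusion matrix, yielding one distribution of values per metric over the
repetitions. The reported interval for the count-based metrics is an exact
Clopper-Pearson binomial interval at the metric's natural denominator; the
AUC interval uses the influence-curve variance estimator for
cross-validated AUC, which accounts for the fold structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

BINOMIAL_METRICS = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FOMSummary:
    """Distributions, means and confidence intervals of the figures of merit.

    ``values`` has one row per repetition and one column per metric;
    ``table`` has one row per metric with columns mean / ci_lo / ci_hi
    (proportions, not percent).
    """

    values: pd.DataFrame
    table: pd.DataFrame
    level: float

    def as_percent(self) -> pd.DataFrame:
        return (self.table * 100).round(1)


def fom_from_confusion(cm: dict) -> dict:
    """Sensitivity, specificity, accuracy, PPV, NPV from a 2x2 confusion
    matrix (positive class fixed by the caller). Zero-denominator metrics
    come back as NaN (undefined), never as 0."""
    tp, fp, tn, fn = (float(cm[k]) for k in ("tp", "fp", "tn", "fn"))
    if min(tp, fp, tn, fn) < 0:
        raise ValueError(f"negative confusion counts: {cm}")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) central confidence interval for a binomial
    proportion, from the beta-quantile closed form."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _confusion_denominators(cm: dict) -> dict:
    tp, fp, tn, fn = (cm[k] for k in ("tp", "fp", "tn", "fn"))
    return {
        "sensitivity": tp + fn,
        "specificity": tn + fp,
        "accuracy": tp + fp + tn + fn,
        "ppv": tp + fp,
        "npv": tn + fn,
    }


def summarize_foms(results, level: float = 0.95) -> FOMSummary:
    """Distribution, mean and CI of every figure of merit over repetitions.

    Count-based metrics get a Clopper-Pearson interval at
    ``x = round(mean * n_denom)`` where ``n_denom`` is the metric's natural
    denominator (positives tested for sensitivity, all samples for
    accuracy, ...; averaged over repetitions where it varies). The AUC row
    uses the cross-validated influence-function interval.
    """
    reps = results.repetitions
    pos = results.config.positive_class
    rows = []
    denom_rows = []
    for rep in reps:
        foms = fom_from_confusion(rep.confusion)
        foms["auc"] = roc_auc_per_repetition(rep, pos).auc
        rows.append(foms)
        denom_rows.append(_confusion_denominators(rep.confusion))
    values = pd.DataFrame(rows)
    denoms = pd.DataFrame(denom_rows)

    table = {}
    for metric in BINOMIAL_METRICS:
        mean = float(values[metric].mean())
        n_denom = int(round(denoms[metric].mean()))
        if np.isnan(mean) or n_denom < 1:
            table[metric] = {"mean": mean, "ci_lo": np.nan, "ci_hi": np.nan}
            continue
        x = int(round(mean * n_denom))
        lo, hi = binomial_ci(x, n_denom, level=level)
        table[metric] = {"mean": mean, "ci_lo": lo, "ci_hi": hi}
    mean_auc, lo, hi = cv_auc_confidence_interval(
        fold_predictions(results, pos), level=level
    )
    table["auc"] = {"mean": mean_auc, "ci_lo": lo, "ci_hi": hi}
    return FOMSummary(values=values, table=pd.DataFrame(table).T, level=level)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc_per_repetition(rep, positive_class) -> ROCCurve:
    """One ROC per repetition, from the per-sample positive-class posteriors
    pooled across the repetition's outer folds. Ties get half credit, so the
    AUC equals the normalized Mann-Whitney statistic."""
    pred = rep.predictions
    truth = (pred["truth"].to_numpy() == positive_class).astype(int)
    scores = pred["posterior"].to_numpy()
    if truth.min() == truth.max():
        raise ValueError("ROC needs both classes in the pooled predictions")
    fpr, tpr, thresholds = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def average_roc(curves: list[ROCCurve], n_grid: int = 201):
    """Mean TPR over repetitions on a fixed FPR grid (the single black
    average trace over the per-repetition curves)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for c in curves:
        # step-interpolate each curve onto the grid
        tprs.append(np.interp(grid, c.fpr, c.tpr))
    return grid, np.vstack(tprs).mean(axis=0)


def fold_predictions(results, positive_class) -> list[tuple[np.ndarray, np.ndarray]]:
    """(scores, binary labels) per outer fold of every repetition — the CV
    fold structure for the cross-validated AUC interval."""
    folds = []
    for rep in results.repetitions:
        for j, fm in enumerate(rep.fold_models):
            mask = rep.predictions["outer_fold"].to_numpy() == j
            scores = rep.predictions.loc[mask, "posterior"].to_numpy()
            labels = (
                rep.predictions.loc[mask, "truth"].to_numpy() == positive_class
            ).astype(int)
            folds.append((scores, labels))
    return folds


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties half credit)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _ecdf_values(sample: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Empirical CDF of ``sample`` evaluated at ``at`` with half weight on
    ties (the tie convention matching the Mann-Whitney AUC)."""
    sample = np.sort(sample)
    less = np.searchsorted(sample, at, side="left")
    leq = np.searchsorted(sample, at, side="right")
    return (less + 0.5 * (leq - less)) / len(sample)


def cv_auc_confidence_interval(
    folds: list[tuple[np.ndarray, np.ndarray]], level: float = 0.95
):
    """Influence-curve Wald interval for the cross-validated AUC.

    Per fold v with empirical score CDFs F0 (negatives), F1 (positives),
    AUC_v and positive fraction p_v, the influence value of an observation
    with label y and score s is::

        IC = y/p_v * (F0(s) - AUC_v) + (1-y)/(1-p_v) * (1 - F1(s) - AUC_v)

    The variance estimate is mean-over-folds of mean(IC^2), divided by the
    total number of scored observations; the point estimate is the mean of
    the per-fold AUCs. The interval is truncated to [0, 1]. Folds with a
    single class are excluded with a warning.
    """
    aucs = []
    ic_means = []
    n_total = 0
    for scores, labels in folds:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn("excluding a CV fold with a single class from the "
                          "AUC interval", RuntimeWarning, stacklevel=2)
            continue
        auc = _auc_mann_whitney(scores, labels)
        p_hat = len(pos) / len(scores)
        f0_at = _ecdf_values(neg, scores)  # F0(s_i)
        f1_at = _ecdf_values(pos, scores)  # F1(s_i)
        ic = (labels / p_hat) * (f0_at - auc) + (
            (1 - labels) / (1 - p_hat)
        ) * (1.0 - f1_at - auc)
        aucs.append(auc)
        ic_means.append(float(np.mean(ic**2)))
        n_total += len(scores)
    if not aucs:
        raise ValueError("no CV fold carried both classes")
    mean_auc = float(np.mean(aucs))
    sighat2 = float(np.mean(ic_means))
    se = np.sqrt(sighat2 / n_total)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, mean_auc - z * se)
    hi = min(1.0, mean_auc + z * se)
    return mean_auc, lo, hi
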