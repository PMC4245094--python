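"""Diagnostic-accuracy and regression layer.

Implements the statistics used to judge MR fat quantification against the
histologic reference: Spearman correlation, empirical (trapezoidal) and
kernel-smoothed robust ROC curves with Youden-index thresholds, the DeLong
test for paired AUC comparison, the Obuchowski AUC for an ordinal gold
standard, ordinary least-squares models of histology steatosis on the MR fat
fraction with steatohepatitis/fibrosis covariates, and per-grade group
summaries with rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr
from scipy.stats import mannwhitneyu, norm, rankdata, spearmanr
from sklearn.metrics import roc_curve as _sk_roc_curve

from .histology import CUTPOINTS, GRADES, binary_labels, grade_rank

__all__ = [
    "RocResult",
    "ThresholdResult",
    "ModelFit",
    "spearman_rho",
    "roc_empirical",
    "roc_smoothed",
    "youden_threshold",
    "compare_roc_paired",
    "obuchowski_auc",
    "fit_steatosis_models",
    "group_summaries",
    "group_test",
    "build_report",
]


@dataclass
class RocResult:
    """ROC curve (fpr, tpr, thresholds) with its area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    smoothed: bool = False


@dataclass
class ThresholdResult:
    """A decision threshold with its operating point and Youden J."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class ModelFit:
    """OLS fit summary: coefficient table, R^2, and the Obuchowski AUC of
    the fitted values against the 4-level steatosis grade."""

    coefficients: pd.DataFrame
    r_squared: float
    obuchowski_auc: float
    obuchowski_se: float
    n_obs: int


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    return x, y


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x, y = _as_xy(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = spearmanr(x, y).statistic
    return float(rho)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pairwise concordance P(pos > neg) + 0.5 P(tie) via midranks."""
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    m, n = len(pos), len(neg)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_empirical(scores, labels) -> RocResult:
    """Empirical ROC over all unique thresholds; AUC by the trapezoidal
    rule, which equals the Mann-Whitney concordance (ties count 1/2)."""
    pos, neg = _split_scores(scores, labels)
    fpr, tpr, thresholds = _sk_roc_curve(
        np.asarray(labels).astype(int), np.asarray(scores, dtype=float),
        drop_intermediate=False,
    )
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     smoothed=False)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 1.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(x).max(), 1.0) * 1e-3
    return 0.9 * scale * n ** (-1 / 5)


def roc_smoothed(scores, labels, bandwidth: float | None = None) -> RocResult:
    """Kernel-smoothed robust ROC.

    Robustness comes from rank-transforming the scores before smoothing;
    each class's score distribution is then smoothed with a Gaussian kernel
    (Silverman bandwidth by default) and the continuous ROC is traced over a
    fine threshold grid. Thresholds are mapped back to the original score
    scale by interpolating the rank transform. As the bandwidth shrinks the
    curve converges to the empirical ROC.
    """
    pos, neg = _split_scores(scores, labels)
    if len(pos) < 5 or len(neg) < 5:
        raise ValueError("need at least 5 subjects per class for smoothing")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels).astype(int)
    ranks = rankdata(scores_arr)
    rpos = ranks[labels_arr == 1]
    rneg = ranks[labels_arr == 0]
    h_pos = bandwidth if bandwidth is not None else _silverman_bandwidth(rpos)
    h_neg = bandwidth if bandwidth is not None else _silverman_bandwidth(rneg)
    lo = ranks.min() - 4 * max(h_pos, h_neg)
    hi = ranks.max() + 4 * max(h_pos, h_neg)
    mids = (np.sort(ranks)[:-1] + np.sort(ranks)[1:]) / 2
    grid = np.unique(np.concatenate([np.linspace(lo, hi, 256), ranks, mids]))

    def survival(centers: np.ndarray, h: float, tgrid: np.ndarray) -> np.ndarray:
        # P(X > t) under the kernel-smoothed distribution
        z = (centers[None, :] - tgrid[:, None]) / h
        return ndtr(z).mean(axis=1)

    tpr = survival(rpos, h_pos, grid)
    fpr = survival(rneg, h_neg, grid)
    # descending threshold ordering gives ascending fpr/tpr
    order = np.argsort(grid)[::-1]
    grid, tpr, fpr = grid[order], tpr[order], fpr[order]
    # map rank thresholds back to the score scale
    sort_idx = np.argsort(scores_arr)
    score_thresholds = np.interp(grid, ranks[sort_idx], scores_arr[sort_idx])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    score_thresholds = np.concatenate(
        [[score_thresholds[0]], score_thresholds, [score_thresholds[-1]]]
    )
    auc = float(np.clip(np.trapezoid(tpr, fpr), 0.0, 1.0))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=score_thresholds, auc=auc,
                     smoothed=True)


def youden_threshold(roc: RocResult) -> ThresholdResult:
    """Threshold maximizing J = sensitivity + specificity - 1; exact ties
    are broken toward the lower threshold."""
    if len(roc.fpr) == 0:
        raise ValueError("empty ROC")
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    j_search = np.where(finite, j, -np.inf)
    jmax = j_search.max()
    tied = np.flatnonzero(j_search >= jmax - 1e-12)
    idx = tied[np.argmin(roc.thresholds[tied])]
    return ThresholdResult(
        threshold=float(roc.thresholds[idx]),
        sensitivity=float(roc.tpr[idx]),
        specificity=float(1.0 - roc.fpr[idx]),
        youden_j=float(roc.tpr[idx] - roc.fpr[idx]),
    )


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n          # structural components, positives
    v01 = 1.0 - (tz[m:] - ty) / m    # structural components, negatives
    return auc, v10, v01


def compare_roc_paired(scores_a, scores_b, labels) -> float:
    """DeLong two-sided test for the difference of two correlated AUCs
    measured on the same subjects. Returns the p-value."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired comparison requires equal-length inputs")
    _split_scores(scores_a, labels)  # validates both classes present
    a1, v10_1, v01_1 = _delong_components(scores_a, labels)
    a2, v10_2, v01_2 = _delong_components(scores_b, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = a1 - a2
    if diff == 0 or var <= 0:
        return 1.0
    z = diff / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def _ordinal_truth(truth) -> np.ndarray:
    truth = np.asarray(truth)
    if truth.dtype.kind in "OUS":
        return np.array([grade_rank(str(g)) for g in truth], dtype=float)
    return truth.astype(float)


def obuchowski_auc(predictions, ordinal_truth) -> tuple[float, float]:
    """Obuchowski AUC for an ordinal gold standard with >= 2 levels.

    Weighted average of all pairwise between-level AUCs, each level pair
    weighted by its number of subject pairs -- equivalently the mean
    concordance kernel over all pairs of subjects with different truth
    levels. The standard error is the leave-one-subject-out jackknife of
    that U-statistic.
    """
    pred = np.asarray(predictions, dtype=float)
    truth = _ordinal_truth(ordinal_truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("predictions and truth must be 1-d of equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("ordinal truth must have at least 2 distinct levels")
    n = len(pred)
    diff = pred[None, :] - pred[:, None]          # [lower, higher]
    kernel = (diff > 0).astype(float) + 0.5 * (diff == 0)
    ordered = truth[None, :] > truth[:, None]
    num = float(kernel[ordered].sum())
    n_pairs = int(ordered.sum())
    theta = num / n_pairs
    # jackknife over subjects
    contrib = (kernel * ordered).sum(axis=1) + (kernel * ordered).sum(axis=0)
    count = ordered.sum(axis=1) + ordered.sum(axis=0)
    keep = (n_pairs - count) > 0
    theta_loo = np.where(keep, (num - contrib) / np.maximum(n_pairs - count, 1), theta)
    se = float(np.sqrt((n - 1) / n * np.sum((theta_loo - theta_loo.mean()) ** 2)))
    return theta, se


_FIBROSIS_DUMMIES = {"F1": "fibrosis_1", "F2": "fibrosis_2",
                     "F3": "fibrosis_3or4", "F4": "fibrosis_3or4"}


def fit_steatosis_models(
    cohort: pd.DataFrame,
    method: str,
    covariates: Sequence[str] | None = None,
    compute_auc: bool = True,
) -> ModelFit:
    """OLS of histology steatosis % on one method's fat fraction.

    The MR fat fraction enters as a proportion in [0, 1] (so a slope near
    30 means 30 histology points per unit fat fraction). Optional covariates:
    ``"nash"`` (steatohepatitis indicator) and ``"fibrosis"`` (indicators for
    F1, F2 and merged F3-or-4, reference F0). Empty factor levels are dropped
    with a warning. The Obuchowski AUC of the fitted values against the
    4-level grade summarizes ordinal discrimination.
    """
    col = f"{method}_pdff_pct"
    if col not in cohort.columns or "histo_pct" not in cohort.columns:
        raise ValueError(f"cohort table must contain columns {col!r} and 'histo_pct'")
    data = cohort.dropna(subset=[col, "histo_pct"]).copy()
    y = data["histo_pct"].astype(float)
    design = pd.DataFrame({"const": 1.0, method: data[col].astype(float) / 100.0},
                          index=data.index)
    for cov in covariates or ():
        if cov == "nash":
            design["nash"] = data["nash_flag"].astype(float)
        elif cov == "fibrosis":
            for stage, name in _FIBROSIS_DUMMIES.items():
                indicator = (data["fibrosis_stage"] == stage).astype(float)
                if name in design:
                    design[name] = design[name] + indicator
                else:
                    design[name] = indicator
            for name in list(design.columns):
                if name.startswith("fibrosis_") and design[name].sum() == 0:
                    warnings.warn(f"dropping empty factor level {name}", stacklevel=2)
                    design = design.drop(columns=name)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "term": design.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )
    if compute_auc:
        auc, se = obuchowski_auc(fit.fittedvalues.to_numpy(),
                                 data["grade"].to_numpy())
    else:
        auc, se = float("nan"), float("nan")
    return ModelFit(
        coefficients=coef,
        r_squared=float(fit.rsquared),
        obuchowski_auc=auc,
        obuchowski_se=se,
        n_obs=int(fit.nobs),
    )


def group_summaries(cohort: pd.DataFrame, value_column: str,
                    by: str = "grade") -> pd.DataFrame:
    """Per-group n, median and (q25, q75) with linear-interpolation quantiles."""
    if value_column not in cohort.columns:
        raise ValueError(f"no column {value_column!r}")
    rows = []
    for grade in GRADES:
        values = cohort.loc[cohort[by] == grade, value_column].dropna().to_numpy()
        if len(values) == 0:
            continue
        rows.append(
            {
                by: grade,
                "n": len(values),
                "median": float(np.median(values)),
                "q25": float(np.quantile(values, 0.25)),
                "q75": float(np.quantile(values, 0.75)),
            }
        )
    return pd.DataFrame(rows)


def group_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def build_report(
    cohort: pd.DataFrame,
    methods: Sequence[str] = ("triple", "multi", "mrs"),
) -> dict:
    """Assemble the full evaluation report from a quantified cohort table.

    Shapes mirror the study outputs: a correlations block, per-method
    per-cutpoint diagnostic accuracy (empirical AUC; Youden threshold,
    sensitivity and specificity from the smoothed robust ROC), per-grade
    medians/IQRs with pairwise rank-sum tests, univariable and multivariable
    linear models, and paired DeLong comparisons between methods.
    """
    report: dict = {"n_subjects": int(len(cohort))}

    correlations = {}
    for method in methods:
        col = f"{method}_pdff_pct"
        sub = cohort.dropna(subset=[col])
        res = spearmanr(sub[col], sub["histo_pct"])
        correlations[method] = {"rho": float(res.statistic),
                                "p_value": float(res.pvalue), "n": int(len(sub))}
    report["correlations"] = correlations

    accuracy: dict = {}
    for method in methods:
        col = f"{method}_pdff_pct"
        accuracy[method] = {}
        sub = cohort.dropna(subset=[col])
        for cut in CUTPOINTS:
            labels = binary_labels(sub["grade"], cut)
            if labels.sum() == 0 or labels.sum() == len(labels):
                accuracy[method][cut] = {"skipped": "one class absent"}
                continue
            scores = sub[col].to_numpy()
            emp = roc_empirical(scores, labels)
            entry = {"auc": emp.auc, "n_positive": int(labels.sum()),
                     "n_negative": int(len(labels) - labels.sum())}
            try:
                thr = youden_threshold(roc_smoothed(scores, labels))
                entry["threshold_source"] = "smoothed"
            except ValueError:
                # too few subjects in a class to smooth: fall back to the
                # empirical ROC for the operating point
                thr = youden_threshold(emp)
                entry["threshold_source"] = "empirical"
            entry.update(
                threshold=thr.threshold,
                sensitivity=thr.sensitivity,
                specificity=thr.specificity,
                youden_j=thr.youden_j,
            )
            accuracy[method][cut] = entry
    report["diagnostic_accuracy"] = accuracy

    summaries: dict = {}
    for method in methods:
        col = f"{method}_pdff_pct"
        table = group_summaries(cohort, col)
        entry = {
            row["grade"]: {"n": int(row["n"]), "median": row["median"],
                           "q25": row["q25"], "q75": row["q75"]}
            for _, row in table.iterrows()
        }
        tests = {}
        present = [g for g in GRADES if (cohort["grade"] == g).sum() >= 2]
        for i, ga in enumerate(present):
            for gb in present[i + 1:]:
                va = cohort.loc[cohort["grade"] == ga, col].dropna()
                vb = cohort.loc[cohort["grade"] == gb, col].dropna()
                if len(va) >= 2 and len(vb) >= 2:
                    tests[f"{ga}_vs_{gb}"] = group_test(va, vb)
        summaries[method] = {"groups": entry, "pairwise_p": tests}
    report["group_summaries"] = summaries

    report["models_univariable"] = {}
    report["models_multivariable"] = {}
    for method in methods:
        uni = fit_steatosis_models(cohort, method)
        multi = fit_steatosis_models(cohort, method, covariates=("nash", "fibrosis"))
        for key, fitted in (("models_univariable", uni), ("models_multivariable", multi)):
            report[key][method] = {
                "coefficients": fitted.coefficients.to_dict(orient="records"),
                "r_squared": fitted.r_squared,
                "obuchowski_auc": fitted.obuchowski_auc,
                "obuchowski_se": fitted.obuchowski_se,
                "n_obs": fitted.n_obs,
            }

    comparisons: dict = {}
    for cut in CUTPOINTS:
        comparisons[cut] = {}
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                cols = [f"{ma}_pdff_pct", f"{mb}_pdff_pct"]
                sub = cohort.dropna(subset=cols)
                labels = binary_labels(sub["grade"], cut)
                if labels.sum() == 0 or labels.sum() == len(labels):
                    comparisons[cut][f"{ma}_vs_{mb}"] = None
                    continue
                comparisons[cut][f"{ma}_vs_{mb}"] = compare_roc_paired(
                    sub[cols[0]], sub[cols[1]], labels
                )
    report["roc_comparisons"] = comparisons
    return report
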