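"""Cohort-level statistics for the imaging measurement tables.

Implements the statistical layer applied to per-subject PD / HC tables:

* two-sided Mann-Whitney U group comparisons (exact enumeration for small
  samples, tie-corrected normal approximation otherwise),
* batteries of Spearman rank correlations with Benjamini-Hochberg FDR
  adjustment,
* ROC analysis with the empirical trapezoid AUC (identical to
  U / (n1 n2)), candidate cut-offs at midpoints between adjacent sorted
  values, the three named operating points (sensitivity-100%,
  specificity-100%, accuracy-maximizing with Youden tie-break) and exact
  Clopper-Pearson 95% confidence intervals,
* ICC(2,1) intra-rater reliability (two-way random effects, absolute
  agreement, single measurement),
* ordinary-least-squares prediction of striatal DAT binding from the NM
  measures, with R^2, RMSE, PRESS and per-predictor p-values.

Orientation matters throughout: NM measures are *reduced* in PD, so ROC
analyses declare ``direction="lower"`` (a value below the cut-off calls
the subject PD). The direction is always declared, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CohortStatsError",
    "GroupComparison",
    "CorrelationReport",
    "CutoffReport",
    "RocResult",
    "IccResult",
    "PredictionReport",
    "group_compare",
    "spearman_battery",
    "clopper_pearson",
    "confusion_at_cutoff",
    "roc_analysis",
    "icc_reliability",
    "predict_dat",
]

GROUPS = ("PD", "HC")


class CohortStatsError(ValueError):
    """Raised for empty groups, degenerate inputs, or bad declarations."""


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    u_statistic: float
    p_value: float
    n_pd: int
    n_hc: int
    method: str  # "exact" | "asymptotic" | "degenerate"


def _group_values(table: pd.DataFrame, measure: str, group: str) -> np.ndarray:
    vals = table.loc[table["group"] == group, measure].dropna().to_numpy(float)
    return vals


def group_compare(table: pd.DataFrame, measure: str) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of PD vs HC for one measure.

    Exact null enumeration when both groups have n <= 8 and there are no
    ties; tie-corrected normal approximation otherwise. All-tied input
    (zero tie-corrected variance) returns p = 1 by convention.
    """
    x = _group_values(table, measure, "PD")
    y = _group_values(table, measure, "HC")
    if len(x) < 2 or len(y) < 2:
        raise CohortStatsError(f"{measure}: each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return GroupComparison(measure, len(x) * len(y) / 2.0, 1.0,
                               len(x), len(y), "degenerate")
    ties = np.unique(pooled).size < pooled.size
    if len(x) <= 8 and len(y) <= 8 and not ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(measure, float(res.statistic), float(min(res.pvalue, 1.0)),
                           len(x), len(y), method)


# --------------------------------------------------------------------------
# Spearman battery with FDR
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationReport:
    x: str
    y: str
    rho: float
    p_value: float
    p_adjusted: float
    significant: bool
    n: int


def spearman_battery(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    group: str | None = None,
) -> list[CorrelationReport]:
    """Spearman rank correlations over a declared battery of variable pairs.

    Mid-rank ties; p-values from the t approximation; Benjamini-Hochberg
    adjustment across the whole battery; flags at adjusted p < ``alpha``.
    ``group`` optionally restricts to one diagnostic group (correlations
    with clinical scores are within-PD in the study design). A constant
    variable yields an undefined rho, reported as NaN and excluded from
    the FDR family.
    """
    sub = table if group is None else table[table["group"] == group]
    raw: list[tuple[str, str, float, float, int]] = []
    for xname, yname in pairs:
        d = sub[[xname, yname]].dropna()
        if len(d) < 4:
            raise CohortStatsError(f"({xname}, {yname}): need >= 4 complete pairs")
        x, y = d[xname].to_numpy(float), d[yname].to_numpy(float)
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            raw.append((xname, yname, np.nan, np.nan, len(d)))
            continue
        rho, p = sps.spearmanr(x, y)
        raw.append((xname, yname, float(rho), float(p), len(d)))
    defined = [r for r in raw if np.isfinite(r[3])]
    adj: dict[tuple[str, str], float] = {}
    if defined:
        _, p_adj, _, _ = multipletests([r[3] for r in defined], method="fdr_bh")
        adj = {(r[0], r[1]): float(p) for r, p in zip(defined, p_adj)}
    out = []
    for xname, yname, rho, p, n in raw:
        pa = adj.get((xname, yname), np.nan)
        out.append(CorrelationReport(xname, yname, rho, p, pa,
                                     bool(np.isfinite(pa) and pa < alpha), n))
    return out


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n."""
    if not 0 <= k <= n or n == 0:
        raise CohortStatsError(f"invalid binomial count {k}/{n}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


@dataclass(frozen=True)
class CutoffReport:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]


@dataclass
class RocResult:
    measure: str
    direction: str
    auc: float
    n_pd: int
    n_hc: int
    cutoffs: pd.DataFrame  # candidate cut-offs with sens/spec/accuracy
    cutoff_sens100: CutoffReport | None
    cutoff_spec100: CutoffReport | None
    cutoff_best_accuracy: CutoffReport | None
    degenerate: bool = False


def confusion_at_cutoff(
    pd_values: np.ndarray,
    hc_values: np.ndarray,
    cutoff: float,
    direction: str = "lower",
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of the threshold classifier.

    ``direction="lower"``: a subject is called PD when the value falls
    strictly below the cut-off; HC at or above it. ``"higher"`` mirrors
    this. Accuracy is (TP + TN) / (n1 + n2).
    """
    pd_values = np.asarray(pd_values, float)
    hc_values = np.asarray(hc_values, float)
    if direction == "lower":
        tp = int(np.sum(pd_values < cutoff))
        tn = int(np.sum(hc_values >= cutoff))
    elif direction == "higher":
        tp = int(np.sum(pd_values > cutoff))
        tn = int(np.sum(hc_values <= cutoff))
    else:
        raise CohortStatsError(f"unknown direction {direction!r}")
    n1, n2 = len(pd_values), len(hc_values)
    return tp / n1, tn / n2, (tp + tn) / (n1 + n2)


def _trapezoid_auc(pd_values: np.ndarray, hc_values: np.ndarray, direction: str) -> float:
    """Empirical ROC AUC by the trapezoid rule (ties contribute half)."""
    score_pd = -pd_values if direction == "lower" else pd_values
    score_hc = -hc_values if direction == "lower" else hc_values
    thresholds = np.unique(np.concatenate([score_pd, score_hc]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(score_pd >= t))
        fpr.append(np.mean(score_hc >= t))
    return float(np.trapezoid(tpr, fpr))


def roc_analysis(
    table: pd.DataFrame,
    measure: str,
    direction: str = "lower",
) -> RocResult:
    """ROC analysis of one measure for discriminating PD from HC.

    Candidate cut-offs are the midpoints between adjacent distinct sorted
    pooled values. Three operating points are named: the lowest cut-off
    reaching 100% sensitivity (all PD on the PD side of it, maximizing
    specificity), the highest reaching 100% specificity (all HC on the HC
    side, maximizing sensitivity), and the accuracy maximizer (ties broken
    by larger Youden J, then by the smaller cut-off). Sensitivity and
    specificity at each named point carry exact Clopper-Pearson 95% CIs.
    Degenerate input (all values equal) is flagged with AUC 0.5.
    """
    x = _group_values(table, measure, "PD")
    y = _group_values(table, measure, "HC")
    if len(x) == 0 or len(y) == 0:
        raise CohortStatsError(f"{measure}: both groups must be present")
    pooled = np.unique(np.concatenate([x, y]))
    if pooled.size == 1:
        return RocResult(measure, direction, 0.5, len(x), len(y),
                         pd.DataFrame(), None, None, None, degenerate=True)
    auc = _trapezoid_auc(x, y, direction)
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    rows = []
    for c in mids:
        sens, spec, acc = confusion_at_cutoff(x, y, c, direction)
        rows.append((float(c), sens, spec, acc, sens + spec - 1.0))
    cand = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity",
                                       "accuracy", "youden"])

    def report(row: pd.Series) -> CutoffReport:
        k_tp = int(round(row.sensitivity * len(x)))
        k_tn = int(round(row.specificity * len(y)))
        return CutoffReport(
            cutoff=float(row.cutoff),
            sensitivity=float(row.sensitivity),
            specificity=float(row.specificity),
            accuracy=float(row.accuracy),
            youden=float(row.youden),
            ci_sensitivity=clopper_pearson(k_tp, len(x)),
            ci_specificity=clopper_pearson(k_tn, len(y)),
        )

    full_sens = cand[cand.sensitivity == 1.0]
    full_spec = cand[cand.specificity == 1.0]
    if direction == "lower":
        # sensitivity grows with the cut-off, specificity shrinks
        c_sens = report(full_sens.loc[full_sens.cutoff.idxmin()]) if len(full_sens) else None
        c_spec = report(full_spec.loc[full_spec.cutoff.idxmax()]) if len(full_spec) else None
    else:
        c_sens = report(full_sens.loc[full_sens.cutoff.idxmax()]) if len(full_sens) else None
        c_spec = report(full_spec.loc[full_spec.cutoff.idxmin()]) if len(full_spec) else None
    best = cand.sort_values(
        ["accuracy", "youden", "cutoff"], ascending=[False, False, True]
    ).iloc[0]
    return RocResult(measure, direction, auc, len(x), len(y), cand,
                     c_sens, c_spec, report(best))


# --------------------------------------------------------------------------
# reliability
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_subjects: int
    n_repeats: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    degenerate: bool = False


def icc_reliability(repeats: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    ``repeats`` is a subjects x repeats matrix. From the two-way ANOVA mean
    squares (rows = subjects, columns = repeats):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero between-subject variance is degenerate and reported as ICC 0 with
    a flag.
    """
    m = np.asarray(repeats, dtype=float)
    if m.ndim != 2:
        raise CohortStatsError("repeats must be a 2-D subjects x repeats matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise CohortStatsError("need >= 3 subjects and >= 2 repeats")
    if np.any(~np.isfinite(m)):
        raise CohortStatsError("repeats matrix contains non-finite entries")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if np.allclose(row_means, row_means[0]) and np.isclose(ss_rows, 0.0):
        return IccResult(0.0, n, k, msr, msc, mse, degenerate=True)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom
    return IccResult(float(icc), n, k, float(msr), float(msc), float(mse))


# --------------------------------------------------------------------------
# least-squares prediction of DAT binding
# --------------------------------------------------------------------------


@dataclass
class PredictionReport:
    response: str
    predictors: list[str]
    n: int
    r_squared: float
    rmse: float
    press: float
    f_pvalue: float
    predictor_pvalues: dict[str, float]
    best_predictor: str
    coefficients: dict[str, float]
    rank_deficient: bool = False


def predict_dat(
    table: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("sn_volume_contra", "cnr_sn_contra", "cnr_lc_contra"),
    group: str | None = "PD",
) -> PredictionReport:
    """OLS prediction of a DAT-binding response from NM-MRI measures.

    Reports R^2, RMSE = sqrt(SSE / (n - p)), the leave-one-out PRESS
    statistic (computed from hat-matrix leverages), the overall F-test
    p-value and per-predictor partial p-values; the best predictor is the
    one with the smallest partial p. Collinear predictors are flagged as
    rank-deficient.
    """
    sub = table if group is None else table[table["group"] == group]
    cols = [response, *predictors]
    d = sub[cols].dropna()
    if len(d) < len(predictors) + 2:
        raise CohortStatsError(
            f"{response}: need >= {len(predictors) + 2} complete cases, got {len(d)}"
        )
    y = d[response].to_numpy(float)
    X = sm.add_constant(d[list(predictors)].to_numpy(float))
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    hat = fit.get_influence().hat_matrix_diag
    press = float(np.sum((resid / (1.0 - hat)) ** 2))
    rmse = float(np.sqrt(np.sum(resid**2) / fit.df_resid))
    pvals = {name: float(p) for name, p in zip(predictors, fit.pvalues[1:])}
    coefs = {"intercept": float(fit.params[0])}
    coefs.update({name: float(b) for name, b in zip(predictors, fit.params[1:])})
    return PredictionReport(
        response=response,
        predictors=list(predictors),
        n=len(d),
        r_squared=float(fit.rsquared),
        rmse=rmse,
        press=press,
        f_pvalue=float(fit.f_pvalue),
        predictor_pvalues=pvals,
        best_predictor=min(pvals, key=pvals.get),
        coefficients=coefs,
        rank_deficient=bool(rank_deficient),
    )
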