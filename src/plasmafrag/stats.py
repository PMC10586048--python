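"""Cohort-level statistics for cfDNA features.

Covers the statistical toolkit used around the fragmentomic features:
mean +/- 4 sd outlier exclusion, rank-based group comparisons
(Mann-Whitney / Kruskal-Wallis), Spearman correlation with kidney function
(eGFR), eGFR-based disease staging, and covariate-adjusted logistic
regression / ROC for single features (adjusting for age, sex and BMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_COVARIATES = ("age", "sex", "bmi")


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------


def remove_outliers(values, k: float = 4.0):
    """Single-pass exclusion of values deviating from the mean by more than
    ``k`` sample standard deviations (ddof=1). Returns (retained values,
    integer indices of the removed observations). With sd == 0 nothing is
    removed."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values")
    mean = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return x[finite], np.array([], dtype=int)
    out = finite & (np.abs(x - mean) > k * sd)
    keep = finite & ~out
    return x[keep], np.flatnonzero(out)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    groups: dict  # label -> dict(n, median, min, max)


def group_compare(
    table: pd.DataFrame,
    feature: str,
    groups: Sequence[str],
    group_col: str = "group",
    exclude_outliers: bool = True,
) -> GroupComparison:
    """Two groups -> two-sided Mann-Whitney U; three -> Kruskal-Wallis.

    Outliers (mean +/- 4 sd over the pooled feature values) are removed
    before testing unless ``exclude_outliers`` is False.
    """
    if len(groups) not in (2, 3):
        raise ValueError("groups must name 2 or 3 labels")
    sub = table[table[group_col].isin(groups)]
    vals = sub[feature].to_numpy(dtype=float)
    lab = sub[group_col].to_numpy()
    finite = np.isfinite(vals)
    vals, lab = vals[finite], lab[finite]
    if exclude_outliers and len(vals) >= 3:
        _, out_idx = remove_outliers(vals)
        keep = np.ones(len(vals), dtype=bool)
        keep[out_idx] = False
        vals, lab = vals[keep], lab[keep]
    samples = [vals[lab == g] for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if len(groups) == 2:
        res = sps.mannwhitneyu(samples[0], samples[1],
                               alternative="two-sided")
        test = "mann-whitney"
    else:
        res = sps.kruskal(*samples)
        test = "kruskal-wallis"
    summary = {
        g: dict(n=len(s), median=float(np.median(s)),
                min=float(s.min()), max=float(s.max()))
        for g, s in zip(groups, samples)
    }
    return GroupComparison(test=test, statistic=float(res.statistic),
                           pvalue=float(res.pvalue), groups=summary)


def categorical_compare(table_counts: np.ndarray) -> tuple[str, float, float]:
    """Chi-square test on a contingency table; Fisher's exact test is used
    instead for 2x2 tables with any expected cell below 5."""
    obs = np.asarray(table_counts, dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        if obs.shape == (2, 2):
            stat, p = sps.fisher_exact(obs)
            return "fisher", float(stat), float(p)
        warnings.warn(
            "expected cell < 5 in a non-2x2 table; chi-square retained",
            stacklevel=2,
        )
    return "chi-square", float(chi2), float(p)


# ---------------------------------------------------------------------------
# eGFR staging and correlation
# ---------------------------------------------------------------------------


def dn_stage(egfr: float) -> int:
    """Kidney-disease stage from eGFR (ml/min/1.73 m^2): >90 -> 1,
    [60, 90] -> 2, [30, 60) -> 3, [15, 30) -> 4, <15 -> 5. Boundary values
    are assigned to the less-severe stage."""
    if not np.isfinite(egfr) or egfr <= 0:
        raise ValueError("eGFR must be positive and finite")
    if egfr > 90:
        return 1
    if egfr >= 60:
        return 2
    if egfr >= 30:
        return 3
    if egfr >= 15:
        return 4
    return 5


def correlate_egfr(
    table: pd.DataFrame,
    feature: str,
    groups: Sequence[str] = ("DM", "DN"),
    group_col: str = "group",
    egfr_col: str = "egfr",
) -> tuple[float, float]:
    """Spearman correlation (average-rank ties) between a feature and eGFR
    within the given groups. Returns (rho, p); (nan, nan) for a constant
    feature."""
    sub = table[table[group_col].isin(groups)]
    x = sub[feature].to_numpy(dtype=float)
    y = sub[egfr_col].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# AUC and adjusted logistic ROC
# ---------------------------------------------------------------------------


def auc_mann_whitney(y_true, scores) -> float:
    """AUC via the Mann-Whitney rank identity (average ranks for ties)."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RocReport:
    auc: float
    coefficient: float
    coef_pvalue: float
    n: int
    adjusted: bool
    penalized: bool


def _encode_sex(values: pd.Series) -> np.ndarray:
    v = values
    if v.dtype.kind in "ifb":
        return v.to_numpy(dtype=float)
    mapping = {"M": 1.0, "F": 0.0, "male": 1.0, "female": 0.0}
    out = v.map(lambda s: mapping.get(str(s), np.nan)).to_numpy(dtype=float)
    if np.isnan(out).any():
        codes, _ = pd.factorize(v)
        out = codes.astype(float)
    return out


def adjusted_roc(
    table: pd.DataFrame,
    feature: str,
    outcome_col: str = "group",
    positive: str = "DN",
    negative: str = "DM",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: bool = True,
) -> RocReport:
    """Covariate-adjusted single-feature ROC.

    Fits logistic regression outcome ~ feature (+ age + sex + BMI when
    ``adjust``) and computes the AUC of the fitted probabilities by the
    Mann-Whitney identity. Perfect separation falls back to an L2-penalized
    fit, flagged in the report.
    """
    import statsmodels.api as sm

    sub = table[table[outcome_col].isin([positive, negative])].copy()
    y = (sub[outcome_col] == positive).to_numpy(dtype=float)
    cols = [sub[feature].to_numpy(dtype=float)]
    if adjust:
        for cov in covariates:
            cols.append(
                _encode_sex(sub[cov]) if cov == "sex"
                else sub[cov].to_numpy(dtype=float)
            )
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    Xc = sm.add_constant(X, has_constant="add")
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = fit.params
            pvalues = fit.pvalues
            converged = bool(fit.mle_retvals.get("converged", True))
            if (
                not converged
                or not np.isfinite(params).all()
                or np.abs(params).max() > 1e3
            ):
                raise RuntimeError("logistic fit diverged (separation?)")
        except Exception:
            penalized = True
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=1000)
            lr.fit(X, y)
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            pvalues = np.full(len(params), np.nan)
    logits = Xc @ params
    probs = 1.0 / (1.0 + np.exp(-logits))
    return RocReport(
        auc=auc_mann_whitney(y, probs),
        coefficient=float(params[1]),
        coef_pvalue=float(pvalues[1]),
        n=len(y),
        adjusted=adjust,
        penalized=penalized,
    )
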