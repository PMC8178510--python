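"""Differential expression, survival screening and 2x2 association statistics.

Tumor-vs-normal differential expression uses a per-feature Welch
t-test on log2 values with BH FDR; a feature absent in more than a
per-group allowance is excluded before testing. The survival screen
dichotomizes each feature at the cohort median and fits a Cox
proportional-hazards model (Newton-Raphson on the partial likelihood
with Efron tie handling, authored here; the log-rank test and
Kaplan-Meier curves come from lifelines). Clinicopathological 2x2
tables are summarised by the cross-product odds ratio with a Wald
p-value, oriented to match a logistic regression of the clinical
outcome on the expression group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_fdr
from .expression import ExpressionMatrix

__all__ = [
    "differential_test",
    "CoxPHModel",
    "CoxPHResults",
    "cox_fit",
    "survival_screen",
    "km_logrank",
    "TwoByTwo",
    "OddsRatioResult",
    "or_2x2",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_test(
    expr: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.01,
    group_max_absent: int = 10,
    paired: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature tumor-vs-normal test on log2 expression.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame (samples x features, log2 scale)
    groups : per-sample labels; the set must be {"tumor", "normal"}.
    fc_threshold : fold-change threshold on the natural scale; a feature
        is called DE iff |log2fc| > log2(fc_threshold) and q < q_threshold.
        Pass a log2 threshold directly via ``fc_threshold=2**x``.
    group_max_absent : features absent (missing or value 0) in MORE than
        this many samples of either group are excluded before testing.
    paired : use a paired t-test on per-sample differences (samples must
        align one-to-one after sorting); default unpaired Welch.

    Returns (results, excluded) DataFrames; results columns are
    ``feature_id, log2fc, t_stat, p, q, n_tumor, n_normal, de``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    groups = groups.loc[values.index]
    t_mask = (groups == "tumor").to_numpy()
    n_mask = (groups == "normal").to_numpy()
    if t_mask.sum() < 2 or n_mask.sum() < 2:
        raise ValueError("both groups need at least 2 samples")

    log2fc_lim = np.log2(fc_threshold)
    rows, excluded = [], []
    for feat in values.columns:
        v = values[feat].to_numpy(dtype=float)
        absent = np.isnan(v) | (v == 0)
        if absent[t_mask].sum() > group_max_absent or absent[n_mask].sum() > group_max_absent:
            excluded.append({"feature_id": feat, "reason": "absent_in_group"})
            continue
        vt = v[t_mask & ~np.isnan(v)]
        vn = v[n_mask & ~np.isnan(v)]
        if len(vt) < 2 or len(vn) < 2:
            excluded.append({"feature_id": feat, "reason": "group_missing"})
            continue
        if paired:
            if len(vt) != len(vn):
                excluded.append({"feature_id": feat, "reason": "unpairable"})
                continue
            t_stat, p = stats.ttest_rel(vt, vn)
        else:
            t_stat, p = stats.ttest_ind(vt, vn, equal_var=False)
        rows.append(
            {
                "feature_id": feat,
                "log2fc": float(vt.mean() - vn.mean()),
                "t_stat": float(t_stat),
                "p": float(p),
                "n_tumor": len(vt),
                "n_normal": len(vn),
            }
        )
    res = pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "t_stat", "p", "n_tumor", "n_normal"]
    )
    if len(res):
        res["q"] = bh_fdr(res["p"].to_numpy())
        res["de"] = (res["q"] < q_threshold) & (res["log2fc"].abs() > log2fc_lim)
    else:
        res["q"] = pd.Series(dtype=float)
        res["de"] = pd.Series(dtype=bool)
    return res, pd.DataFrame(excluded, columns=["feature_id", "reason"])


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Efron ties)
# ---------------------------------------------------------------------------

def _efron_loglik(beta: float, x, time, event):
    """Partial log-likelihood, gradient and Hessian at beta (arrays sorted by time)."""
    w = np.exp(beta * x)
    cs0 = np.cumsum(w[::-1])[::-1]
    cs1 = np.cumsum((w * x)[::-1])[::-1]
    cs2 = np.cumsum((w * x * x)[::-1])[::-1]
    ll = grad = hess = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dmask = event[i:j] == 1
        d = int(dmask.sum())
        if d:
            xd = x[i:j][dmask]
            wd = w[i:j][dmask]
            s0d, s1d, s2d = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
            ll += beta * xd.sum()
            grad += xd.sum()
            for ell in range(d):
                f = ell / d
                phi0 = cs0[i] - f * s0d
                phi1 = cs1[i] - f * s1d
                phi2 = cs2[i] - f * s2d
                ll -= np.log(phi0)
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - (phi1 / phi0) ** 2
        i = j
    return ll, grad, hess


@dataclass
class CoxPHResults:
    """Fitted single-covariate Cox model."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    separation: bool

    def summary(self) -> str:
        flag = "  [monotone likelihood: beta capped]" if self.separation else ""
        return (
            "Cox proportional hazards (Efron ties)\n"
            f"n = {self.n}, events = {self.n_events}\n"
            f"log HR = {self.beta:.4f} (se {self.se:.4f}){flag}\n"
            f"HR = {self.hr:.4f}  95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]"
            f"  p = {self.p:.3g}"
        )


class CoxPHModel:
    """Single-covariate Cox proportional-hazards model.

    Fitted by Newton-Raphson on the partial likelihood with Efron
    handling of tied event times and step-halving; a monotone
    likelihood (complete separation) is flagged and the coefficient
    capped rather than diverging.
    """

    BETA_CAP = 20.0

    def __init__(self, covariate, time, event) -> None:
        x = np.asarray(covariate, dtype=float)
        t = np.asarray(time, dtype=float)
        e = np.asarray(event, dtype=int)
        if not (len(x) == len(t) == len(e)):
            raise ValueError("covariate, time and event must align")
        ok = ~(np.isnan(x) | np.isnan(t))
        x, t, e = x[ok], t[ok], e[ok]
        if (t <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if e.sum() < 2:
            raise ValueError("at least 2 events required")
        order = np.argsort(t, kind="stable")
        self.x, self.time, self.event = x[order], t[order], e[order]

    def fit(self, max_iter: int = 50, tol: float = 1e-9) -> CoxPHResults:
        x, t, e = self.x, self.time, self.event
        if np.ptp(x) == 0:
            raise ValueError("covariate is constant")
        beta = 0.0
        separation = False
        converged = False
        ll, grad, hess = _efron_loglik(beta, x, t, e)
        for _ in range(max_iter):
            if hess >= 0:  # degenerate curvature
                break
            step = -grad / hess
            # step-halving to guarantee ascent
            new_beta = beta + step
            for _ in range(30):
                new_ll, new_grad, new_hess = _efron_loglik(new_beta, x, t, e)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    break
                step /= 2.0
                new_beta = beta + step
            if abs(new_beta) > self.BETA_CAP:
                separation = True
                beta = float(np.sign(new_beta) * self.BETA_CAP)
                ll, grad, hess = _efron_loglik(beta, x, t, e)
                break
            delta = abs(new_beta - beta)
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            if delta < tol:
                converged = True
                break
        se = float(np.sqrt(-1.0 / hess)) if hess < 0 else float("inf")
        z = beta / se if se > 0 and np.isfinite(se) else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        half = 1.959963984540054 * se
        with np.errstate(over="ignore"):  # capped beta with infinite se
            ci = (float(np.exp(beta - half)), float(np.exp(beta + half)))
        return CoxPHResults(
            beta=float(beta),
            se=se,
            hr=float(np.exp(beta)),
            ci_low=ci[0],
            ci_high=ci[1],
            p=p,
            n=len(x),
            n_events=int(e.sum()),
            converged=converged,
            separation=separation,
        )


def cox_fit(expr_value, survival: pd.DataFrame) -> CoxPHResults:
    """Cox fit of survival on one covariate (group indicator or continuous).

    ``survival`` must carry ``time`` and ``event`` columns aligned to
    ``expr_value``.
    """
    return CoxPHModel(expr_value, survival["time"], survival["event"]).fit()


def survival_screen(
    expr: ExpressionMatrix | pd.DataFrame,
    survival: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Median-split Cox screen over every feature.

    Each feature is dichotomized at its cohort median (high = value
    strictly above the median); the hazard ratio is high vs low.
    Returns ``feature_id, hr, ci_low, ci_high, p, q, significant``;
    features that cannot be fitted get NaN statistics.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    surv = survival.loc[values.index]
    rows = []
    for feat in values.columns:
        v = values[feat].to_numpy(dtype=float)
        med = np.nanmedian(v)
        group = (v > med).astype(float)
        group[np.isnan(v)] = np.nan
        try:
            r = CoxPHModel(group, surv["time"], surv["event"]).fit()
            rows.append(
                {
                    "feature_id": feat,
                    "hr": r.hr,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                }
            )
        except ValueError:
            rows.append(
                {"feature_id": feat, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            )
    out = pd.DataFrame(rows, columns=["feature_id", "hr", "ci_low", "ci_high", "p"])
    fitted = out["p"].notna()
    out["q"] = np.nan
    if fitted.any():
        out.loc[fitted, "q"] = bh_fdr(out.loc[fitted, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def km_logrank(group_labels, survival: pd.DataFrame):
    """Two-group Kaplan-Meier estimate and log-rank test.

    Returns ``(chi_square, p, km_curves)`` where ``km_curves`` maps each
    group label to its Kaplan-Meier survival-function DataFrame.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    labels = np.asarray(group_labels)
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=int)
    uniq = sorted(pd.unique(labels[pd.notna(labels)]))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if event.sum() < 1:
        raise ValueError("at least one event required")
    m0, m1 = labels == uniq[0], labels == uniq[1]
    res = logrank_test(time[m0], time[m1], event_observed_A=event[m0], event_observed_B=event[m1])
    curves = {}
    for lab, m in zip(uniq, (m0, m1)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        curves[lab] = kmf.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


# ---------------------------------------------------------------------------
# 2x2 clinicopathological association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-outcome table.

    Layout: rows are outcome levels, columns exposure levels, with
    ``a`` = exposed & outcome-numerator, ``b`` = unexposed &
    outcome-numerator, ``c`` = exposed & reference, ``d`` = unexposed &
    reference; OR = (a d) / (b c).
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("outcome", "reference")
    col_labels: tuple[str, str] = ("exposed", "unexposed")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total is zero")


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    p_value: float
    zero_cell: bool


def or_2x2(t: TwoByTwo, haldane: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio of a 2x2 table with a Wald p-value.

    OR = (a d)/(b c), equal to the exponentiated slope of a logistic
    regression of the outcome on the binary exposure. The Wald p uses
    se(log OR) = sqrt(1/a + 1/b + 1/c + 1/d). With a zero cell and
    ``haldane`` False (default) no correction is applied: the OR is
    reported as 0 or inf with ``zero_cell`` set and p = NaN; with
    ``haldane`` True, 0.5 is added to every cell.
    """
    a, b, c, d = (float(v) for v in (t.a, t.b, t.c, t.d))
    if haldane and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if 0.0 in (a, b, c, d):
        num_zero = a == 0 or d == 0
        den_zero = b == 0 or c == 0
        if num_zero and den_zero:
            return OddsRatioResult(float("nan"), float("nan"), True)
        return OddsRatioResult(0.0 if num_zero else float("inf"), float("nan"), True)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_) / se
    return OddsRatioResult(float(or_), float(2.0 * stats.norm.sf(abs(z))), False)
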