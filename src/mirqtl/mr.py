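"""Instrumental-variable (Mendelian randomization) target screening.

An eSNP serves as the genetic instrument for its miRNA; the causal
effect of the miRNA on a candidate mRNA is estimated by the
single-instrument Wald ratio

    b1_IV = cov(G, mRNA) / cov(G, miRNA)

which is numerically identical to two-stage least squares with one
instrument. Instrument strength is assessed by the first-stage F
statistic F = (n-2) R^2 / (1 - R^2) of the miRNA-on-dosage regression;
"significant instrument" means rejection of the zero-first-stage null
at BH FDR < 0.05 across tested axes.

The candidate funnel then applies, in order: (a) target-prediction
integrated score >= 0.1, (b) >= 100 present calls in the cohort,
(c) the weak-instrument screen, (d) tumor-vs-normal differential
expression, (e) survival predictivity; BH FDR is applied within
stages (c), (d) and (e) separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_fdr

__all__ = [
    "WeakInstrumentError",
    "IvEstimate",
    "wald_iv",
    "weak_instrument_f",
    "iv_scan",
    "FunnelThresholds",
    "FunnelReport",
    "run_funnel",
]

#: relative tolerance below which cov(g, x) is treated as numerically zero
_COV_RTOL = 1e-10


class WeakInstrumentError(ValueError):
    """The instrument carries no usable first-stage signal (cov ~ 0)."""


@dataclass
class IvEstimate:
    """Wald-ratio IV estimate for one (eSNP, miRNA, mRNA) axis."""

    snp_id: str
    mirna_id: str
    mrna_id: str
    beta1_iv: float
    se: float
    p_value: float
    first_stage_f: float
    p_weak: float
    n_used: int
    q_weak: float | None = None


def _complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    ok = ~np.any([np.isnan(a) for a in arrays], axis=0)
    return tuple(a[ok] for a in arrays)


def weak_instrument_f(g, x) -> tuple[float, float]:
    """First-stage F statistic and p-value of the exposure-on-instrument fit.

    F = (n - 2) R^2 / (1 - R^2) with the upper-tail p on (1, n-2)
    degrees of freedom; a perfect first stage returns F = +inf, p = 0.
    """
    g, x = _complete(g, x)
    n = len(g)
    if n < 10:
        raise ValueError(f"only {n} pairwise-complete samples; 10 required")
    if np.ptp(g) == 0:
        raise WeakInstrumentError("constant instrument")
    r = np.corrcoef(g, x)[0, 1] if np.ptp(x) > 0 else 0.0
    r2 = r * r
    if 1.0 - r2 < 1e-12:  # perfect first stage up to rounding
        return float("inf"), 0.0
    f = (n - 2) * r2 / (1.0 - r2)
    return float(f), float(stats.f.sf(f, 1, n - 2))


def wald_iv(g, x, y, snp_id: str = "", mirna_id: str = "", mrna_id: str = "") -> IvEstimate:
    """Single-instrument Wald-ratio estimate of the exposure -> outcome effect.

    Parameters
    ----------
    g : instrument (allele dosage)
    x : exposure (miRNA log2 expression)
    y : outcome (mRNA log2 expression)

    The estimate is cov(g, y)/cov(g, x); its standard error is the
    standard 2SLS/delta-method form

        se^2 = s_u^2 * S_gg / S_gx^2,   u = y - ybar - b1 (x - xbar)

    with S_gg, S_gx centred sums of squares / cross-products. A
    first-stage covariance below numerical tolerance raises
    WeakInstrumentError; a merely weak (low-F) instrument passes
    through with its statistics.
    """
    g, x, y = _complete(g, x, y)
    n = len(g)
    if n < 10:
        raise ValueError(f"only {n} pairwise-complete samples; 10 required")
    if np.ptp(g) == 0:
        raise WeakInstrumentError("constant instrument")
    gc, xc, yc = g - g.mean(), x - x.mean(), y - y.mean()
    s_gx = float(gc @ xc)
    s_gg = float(gc @ gc)
    scale = np.sqrt(s_gg * float(xc @ xc))
    if scale == 0 or abs(s_gx) < _COV_RTOL * scale:
        raise WeakInstrumentError("first-stage covariance is numerically zero")
    beta = float(gc @ yc) / s_gx
    u = yc - beta * xc
    sigma2 = float(u @ u) / (n - 2)
    se = float(np.sqrt(sigma2 * s_gg / s_gx**2))
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(2.0 * stats.t.sf(abs(t), n - 2)) if np.isfinite(t) else 0.0
    f_stat, p_weak = weak_instrument_f(g, x)
    return IvEstimate(
        snp_id=snp_id,
        mirna_id=mirna_id,
        mrna_id=mrna_id,
        beta1_iv=beta,
        se=se,
        p_value=p,
        first_stage_f=f_stat,
        p_weak=p_weak,
        n_used=n,
    )


def iv_scan(
    genotypes,
    mirna,
    mrna,
    axes: pd.DataFrame,
) -> pd.DataFrame:
    """Wald-ratio IV over a table of (snp_id, mirna_id, mrna_id) axes.

    Samples are intersected across the three inputs; BH q-values for
    the weak-instrument p are attached across all fitted axes. Axes
    that cannot be fitted (undefined instrument, too few samples,
    feature absent) are returned with NaN statistics and a reason.
    """
    shared = [
        s
        for s in genotypes.sample_ids
        if s in set(mirna.sample_ids) and s in set(mrna.sample_ids)
    ]
    gsub = np.array([genotypes.sample_ids.index(s) for s in shared], dtype=int)
    rows = []
    for rec in axes.itertuples(index=False):
        reason = ""
        est = None
        try:
            g = genotypes.dosage_of(rec.snp_id)[gsub]
            x = mirna.values.loc[shared, rec.mirna_id].to_numpy(dtype=float)
            y = mrna.values.loc[shared, rec.mrna_id].to_numpy(dtype=float)
            est = wald_iv(g, x, y, rec.snp_id, rec.mirna_id, rec.mrna_id)
        except (KeyError, ValueError) as exc:
            reason = str(exc) or type(exc).__name__
        rows.append(
            {
                "snp_id": rec.snp_id,
                "mirna_id": rec.mirna_id,
                "mrna_id": rec.mrna_id,
                "beta1_iv": est.beta1_iv if est else np.nan,
                "se": est.se if est else np.nan,
                "p_value": est.p_value if est else np.nan,
                "first_stage_f": est.first_stage_f if est else np.nan,
                "p_weak": est.p_weak if est else np.nan,
                "n_used": est.n_used if est else 0,
                "reason": reason,
            }
        )
    out = pd.DataFrame(rows)
    fitted = out["p_weak"].notna()
    out["q_weak"] = np.nan
    if fitted.any():
        out.loc[fitted, "q_weak"] = bh_fdr(out.loc[fitted, "p_weak"].to_numpy())
    return out


@dataclass(frozen=True)
class FunnelThresholds:
    """Thresholds of the five-stage candidate funnel."""

    min_score: float = 0.1
    min_present: int = 100
    mr_fdr: float = 0.05
    de_fdr: float = 0.01
    de_log2fc: float = 0.5
    survival_fdr: float = 0.05


@dataclass
class FunnelReport:
    """Per-stage survivor counts and per-gene pass/fail flags."""

    stages: pd.DataFrame  # columns: stage, n_in, n_out
    flags: pd.DataFrame  # index gene; pass_a..pass_e, reason columns

    def survivors(self) -> list[str]:
        passed = self.flags[[c for c in self.flags.columns if c.startswith("pass_")]]
        return list(self.flags.index[passed.all(axis=1)])

    def summary(self) -> str:
        lines = ["candidate-gene screening funnel", "=" * 40]
        for rec in self.stages.itertuples(index=False):
            lines.append(f"{rec.stage:<28} {rec.n_in:>5} -> {rec.n_out}")
        lines.append(f"{'final survivors':<28} {len(self.survivors()):>13}")
        return "\n".join(lines)


STAGE_NAMES = (
    "a_integrated_score",
    "b_present_calls",
    "c_mr_instrument",
    "d_differential_expression",
    "e_survival",
)


def run_funnel(
    candidates: pd.DataFrame,
    present_calls: pd.Series,
    iv_results: pd.DataFrame,
    de_results: pd.DataFrame,
    survival_results: pd.DataFrame,
    thresholds: FunnelThresholds = FunnelThresholds(),
) -> FunnelReport:
    """Apply the five-criterion candidate screen in its fixed order.

    Parameters
    ----------
    candidates : DataFrame with columns ``gene, integrated_score``.
    present_calls : per-gene count of samples with detectable expression.
    iv_results : axis-level IV table (as from :func:`iv_scan`) with
        ``mrna_id`` and ``p_weak``; a gene passes the MR stage if any of
        its axes has weak-instrument q < ``mr_fdr``, with BH applied
        across the axes of genes reaching this stage.
    de_results : DataFrame with ``feature_id, log2fc, p`` (p re-adjusted
        within-stage); pass iff q < ``de_fdr`` and \\|log2fc\\| > ``de_log2fc``.
    survival_results : DataFrame with ``feature_id, p`` from the
        survival screen; pass iff within-stage q < ``survival_fdr``.

    Genes missing a statistic at a stage fail that stage with reason
    "missing"; they never silently pass. The result is invariant to
    candidate row order (genes are processed sorted).
    """
    genes = sorted(candidates["gene"].astype(str))
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in candidate table")
    score = candidates.set_index("gene")["integrated_score"]

    flags = pd.DataFrame(index=pd.Index(genes, name="gene"))
    reasons = {g: "" for g in genes}
    stage_counts = []

    # (a) integrated score
    alive = []
    for g in genes:
        ok = bool(score[g] >= thresholds.min_score) if pd.notna(score[g]) else False
        flags.loc[g, "pass_a"] = ok
        if ok:
            alive.append(g)
        elif not reasons[g]:
            reasons[g] = "integrated_score"
    stage_counts.append(("a_integrated_score", len(genes), len(alive)))

    # (b) present calls
    nxt = []
    flags["pass_b"] = False
    for g in alive:
        if g not in present_calls.index or pd.isna(present_calls[g]):
            reasons[g] = reasons[g] or "missing"
            continue
        if present_calls[g] >= thresholds.min_present:
            flags.loc[g, "pass_b"] = True
            nxt.append(g)
        else:
            reasons[g] = reasons[g] or "present_calls"
    stage_counts.append(("b_present_calls", len(alive), len(nxt)))
    alive = nxt

    # (c) MR weak-instrument screen: BH across axes of genes at this stage
    flags["pass_c"] = False
    axes = iv_results[iv_results["mrna_id"].isin(alive) & iv_results["p_weak"].notna()]
    q_axis = pd.Series(dtype=float)
    if len(axes):
        q_axis = pd.Series(bh_fdr(axes["p_weak"].to_numpy()), index=axes.index)
    nxt = []
    for g in alive:
        g_axes = axes.index[axes["mrna_id"] == g]
        if len(g_axes) == 0:
            reasons[g] = reasons[g] or "missing"
            continue
        if (q_axis.loc[g_axes] < thresholds.mr_fdr).any():
            flags.loc[g, "pass_c"] = True
            nxt.append(g)
        else:
            reasons[g] = reasons[g] or "weak_instrument"
    stage_counts.append(("c_mr_instrument", len(alive), len(nxt)))
    alive = nxt

    # (d) differential expression: BH within stage
    flags["pass_d"] = False
    de = de_results.set_index("feature_id") if "feature_id" in de_results else de_results
    de_sub = de.loc[[g for g in alive if g in de.index]]
    q_de = pd.Series(bh_fdr(de_sub["p"].to_numpy()), index=de_sub.index) if len(de_sub) else pd.Series(dtype=float)
    nxt = []
    for g in alive:
        if g not in de_sub.index or pd.isna(de_sub.loc[g, "p"]):
            reasons[g] = reasons[g] or "missing"
            continue
        ok = q_de[g] < thresholds.de_fdr and abs(de_sub.loc[g, "log2fc"]) > thresholds.de_log2fc
        if ok:
            flags.loc[g, "pass_d"] = True
            nxt.append(g)
        else:
            reasons[g] = reasons[g] or "not_differentially_expressed"
    stage_counts.append(("d_differential_expression", len(alive), len(nxt)))
    alive = nxt

    # (e) survival: BH within stage
    flags["pass_e"] = False
    surv = (
        survival_results.set_index("feature_id")
        if "feature_id" in survival_results
        else survival_results
    )
    surv_sub = surv.loc[[g for g in alive if g in surv.index]]
    q_surv = (
        pd.Series(bh_fdr(surv_sub["p"].to_numpy()), index=surv_sub.index)
        if len(surv_sub)
        else pd.Series(dtype=float)
    )
    nxt = []
    for g in alive:
        if g not in surv_sub.index or pd.isna(surv_sub.loc[g, "p"]):
            reasons[g] = reasons[g] or "missing"
            continue
        if q_surv[g] < thresholds.survival_fdr:
            flags.loc[g, "pass_e"] = True
            nxt.append(g)
        else:
            reasons[g] = reasons[g] or "not_survival_predictive"
    stage_counts.append(("e_survival", len(alive), len(nxt)))

    flags["reason"] = [reasons[g] for g in genes]
    for c in [c for c in flags.columns if c.startswith("pass_")]:
        flags[c] = flags[c].astype(bool)
    stages = pd.DataFrame(stage_counts, columns=["stage", "n_in", "n_out"])
    return FunnelReport(stages=stages, flags=flags)
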