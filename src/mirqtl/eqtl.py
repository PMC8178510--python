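"""Covariate-adjusted cis-eQTL mapping.

For every (SNP, miRNA) pair whose transcription-start anchor lies
within a fixed window of the SNP, the expression level is regressed on
allele dosage with age, sex, copy-number category and promoter-
methylation category as covariates:

    miRNA_i = b0 + b1 G_i + b2 Age_i + b3 Sex_i + b4 CNV_i + b5 CpG_i + e_i

The dosage coefficient b1, its t statistic and two-sided p-value come
from the ordinary-least-squares fit on pairwise-complete samples;
Benjamini-Hochberg q-values are computed jointly across all tested
pairs, and associations are called at FDR 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CovariateTable, ExpressionMatrix
from .genotype import GenotypeMatrix

__all__ = ["bh_fdr", "CisEqtlModel", "CisEqtlResults", "scan_cis"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone non-decreasing in p and capped at 1. Raises on p outside
    [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class CisEqtlModel:
    """cis-eQTL scan model over a genotype matrix and an expression matrix.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    expression : ExpressionMatrix
        Feature coordinates must be populated; the anchor used for the
        cis distance is the transcription start (start on '+', end on
        '-' strand).
    covariates : CovariateTable or None
        When None the model reduces to expression ~ dosage.
    window : int
        cis window in bp either side of the SNP (default 1 Mb).
    min_samples : int
        Minimum pairwise-complete samples for a pair to be fitted.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        expression: ExpressionMatrix,
        covariates: CovariateTable | None = None,
        window: int = 1_000_000,
        min_samples: int = 10,
    ) -> None:
        if window <= 0:
            raise ValueError("window must be positive")
        shared = [s for s in genotypes.sample_ids if s in set(expression.sample_ids)]
        if covariates is not None:
            shared = [s for s in shared if s in set(covariates.sample_ids)]
        if len(shared) < min_samples:
            raise ValueError(
                f"only {len(shared)} samples shared across inputs; "
                f"{min_samples} required"
            )
        self.genotypes = genotypes
        self.expression = expression
        self.covariates = covariates
        self.window = int(window)
        self.min_samples = int(min_samples)
        self.sample_ids = shared

    def pairs(self) -> list[tuple[int, str]]:
        """(variant row, feature id) pairs inside the cis window."""
        out = []
        coords = self.expression.coords
        chrom = self.genotypes.variants["chrom"].to_numpy()
        pos = self.genotypes.variants["pos"].to_numpy()
        anchors = []
        for f in self.expression.feature_ids:
            if f not in coords.index:
                continue
            anchors.append((f, *self.expression.anchor(f)))
        for i in range(self.genotypes.n_variants):
            for f, fchrom, fpos in anchors:
                if fchrom == chrom[i] and abs(fpos - int(pos[i])) <= self.window:
                    out.append((i, f))
        return out

    def fit(self, fdr: float = 0.1) -> "CisEqtlResults":
        """Fit every cis pair by OLS and attach joint BH q-values."""
        gsub = np.array(
            [self.genotypes.sample_ids.index(s) for s in self.sample_ids], dtype=int
        )
        expr = self.expression.values.loc[self.sample_ids]
        n_cov = 4 if self.covariates is not None else 0
        cov_cache: dict[str, np.ndarray] = {}

        rows, skipped = [], []
        for vrow, feat in self.pairs():
            g = self.genotypes.dosages[vrow, gsub]
            y = expr[feat].to_numpy(dtype=float)
            if n_cov:
                if feat not in cov_cache:
                    cov_cache[feat] = (
                        self.covariates.for_feature(feat)
                        .loc[self.sample_ids]
                        .to_numpy(dtype=float)
                    )
                C = cov_cache[feat]
                X = np.column_stack([np.ones_like(g), g, C])
            else:
                X = np.column_stack([np.ones_like(g), g])
            ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
            Xo, yo = X[ok], y[ok]
            n_used = int(ok.sum())
            snp_id = self.genotypes.variants["id"].iloc[vrow]
            fchrom, fpos = self.expression.anchor(feat)
            distance = int(self.genotypes.variants["pos"].iloc[vrow]) - fpos

            if n_used < max(self.min_samples, X.shape[1] + 2):
                skipped.append({"snp_id": snp_id, "mirna_id": feat, "reason": "too few samples"})
                continue
            if np.ptp(Xo[:, 1]) == 0:
                skipped.append({"snp_id": snp_id, "mirna_id": feat, "reason": "constant genotype"})
                continue
            beta, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
            if rank < Xo.shape[1]:
                skipped.append({"snp_id": snp_id, "mirna_id": feat, "reason": "collinear design"})
                continue
            resid = yo - Xo @ beta
            dof = n_used - Xo.shape[1]
            sigma2 = float(resid @ resid) / dof
            xtx_inv = np.linalg.inv(Xo.T @ Xo)
            se1 = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
            t_stat = beta[1] / se1 if se1 > 0 else np.inf * np.sign(beta[1])
            p = float(2.0 * stats.t.sf(abs(t_stat), dof)) if np.isfinite(t_stat) else 0.0
            rows.append(
                {
                    "snp_id": snp_id,
                    "mirna_id": feat,
                    "beta1": float(beta[1]),
                    "t_stat": float(t_stat),
                    "p_value": p,
                    "n_used": n_used,
                    "distance": distance,
                }
            )

        assoc = pd.DataFrame(
            rows,
            columns=["snp_id", "mirna_id", "beta1", "t_stat", "p_value", "n_used", "distance"],
        )
        if len(assoc):
            assoc["q_value"] = bh_fdr(assoc["p_value"].to_numpy())
            assoc["abs_t"] = assoc["t_stat"].abs()
            assoc = (
                assoc.sort_values(
                    ["p_value", "abs_t", "snp_id", "mirna_id"],
                    ascending=[True, False, True, True],
                    kind="stable",
                )
                .drop(columns="abs_t")
                .reset_index(drop=True)
            )
        else:
            assoc["q_value"] = pd.Series(dtype=float)
        return CisEqtlResults(assoc, pd.DataFrame(skipped), fdr=fdr, model=self)


class CisEqtlResults:
    """Fitted cis-eQTL scan: per-pair estimates, q-values, diagnostics."""

    def __init__(
        self,
        associations: pd.DataFrame,
        skipped: pd.DataFrame,
        fdr: float = 0.1,
        model: CisEqtlModel | None = None,
    ) -> None:
        self.associations = associations
        self.skipped = skipped
        self.fdr = fdr
        self.model = model

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """Associations called at the given (default configured) FDR."""
        thr = self.fdr if fdr is None else fdr
        return self.associations[self.associations["q_value"] <= thr].reset_index(drop=True)

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "cis-eQTL scan",
            "=" * 45,
            f"pairs tested:        {len(self.associations)}",
            f"pairs skipped:       {len(self.skipped)}",
            f"FDR threshold:       {self.fdr}",
            f"significant pairs:   {len(sig)}",
            f"distinct eSNPs:      {sig['snp_id'].nunique() if len(sig) else 0}",
            f"distinct eMiRs:      {sig['mirna_id'].nunique() if len(sig) else 0}",
        ]
        if len(sig):
            lines.append("-" * 45)
            head = sig.head(10)[["snp_id", "mirna_id", "beta1", "p_value", "q_value"]]
            lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)


def scan_cis(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable | None = None,
    window: int = 1_000_000,
    fdr: float = 0.1,
) -> CisEqtlResults:
    """Functional wrapper: fit the cis-eQTL model over all cis pairs."""
    return CisEqtlModel(genotypes, expression, covariates, window=window).fit(fdr=fdr)
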