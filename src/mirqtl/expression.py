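"""Expression matrices, outlier/missingness rules and covariate coding.

Small-RNA expression arrives as RPM (reads per million); it is
log2(RPM+1)-transformed, per-feature outliers beyond a standard
deviation limit are masked, and features absent in too many samples
are dropped. Somatic copy-number segments are collapsed to a
gain/neutral/loss ordinal and promoter CpG methylation (TSS200/TSS1500
probe beta values) to a 0-3 ordinal; both enter the cis-eQTL model as
single numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "prepare_expression",
    "categorize_cnv",
    "categorize_methylation",
]


@dataclass
class ExpressionMatrix:
    """Samples x features log2-scale expression with an explicit missing mask.

    ``values`` is a DataFrame (rows = samples, columns = features) on
    the log2(RPM+1) scale; NaN marks a masked/missing entry. ``coords``
    gives 1-based feature coordinates (``chrom, start, end, strand``)
    indexed by feature id; it may be empty for matrices that are never
    positionally matched.
    """

    values: pd.DataFrame
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.coords is None:
            self.coords = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite where not missing")
        if len(self.coords):
            if (self.coords["start"] > self.coords["end"]).any():
                raise ValueError("feature coordinates require start <= end")
            if (self.coords["start"] < 1).any():
                raise ValueError("feature coordinates are 1-based")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def anchor(self, feature: str) -> tuple[str, int]:
        """Transcription-start anchor: start on '+' strand, end on '-'."""
        row = self.coords.loc[feature]
        pos = int(row["start"] if row.get("strand", "+") != "-" else row["end"])
        return str(row["chrom"]), pos

    def present_calls(self) -> pd.Series:
        """Per-feature count of samples with detectable expression.

        A present call is a non-missing value strictly greater than 0
        (log2(RPM+1) = 0 iff RPM = 0).
        """
        return ((self.values > 0) & self.values.notna()).sum(axis=0)


@dataclass
class CovariateTable:
    """Per-sample covariates of the cis-eQTL model.

    ``age`` in years and ``sex`` coded 0/1 are per sample; ``cnv``
    (categories -1/0/+1) and ``cpg`` (0-3) are per (sample, feature)
    DataFrames aligned to the expression matrix, since copy number and
    promoter methylation are feature-specific.
    """

    age: pd.Series
    sex: pd.Series
    cnv: pd.DataFrame
    cpg: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(pd.unique(self.sex.dropna())) <= {0, 1}:
            raise ValueError("sex must be coded 0/1")
        if len(self.cnv) and not set(pd.unique(self.cnv.values.ravel())) <= {-1, 0, 1}:
            raise ValueError("cnv categories must be in {-1, 0, +1}")
        if len(self.cpg) and not set(pd.unique(self.cpg.values.ravel())) <= {0, 1, 2, 3}:
            raise ValueError("cpg categories must be in {0, 1, 2, 3}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.age.index)

    def for_feature(self, feature: str) -> pd.DataFrame:
        """Covariate design columns (age, sex, cnv, cpg) for one feature."""
        out = pd.DataFrame({"age": self.age, "sex": self.sex})
        out["cnv"] = self.cnv[feature] if feature in self.cnv.columns else 0
        out["cpg"] = self.cpg[feature] if feature in self.cpg.columns else 0
        return out


def prepare_expression(
    raw_rpm: pd.DataFrame,
    max_absent: int = 20,
    sd_limit: float = 3.0,
    coords: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """log2-transform RPM, mask outliers, drop widely absent features.

    Parameters
    ----------
    raw_rpm : DataFrame
        Non-negative RPM values, rows = samples, columns = features.
    max_absent : int
        Features with RPM exactly 0 in MORE than this many samples are
        dropped (default 20, the small-RNA screening rule; pass 10 per
        group for the differential-expression stage).
    sd_limit : float
        Per feature, entries with \\|value - mean\\| > sd_limit * SD are
        masked missing in a single pass (mean/SD from all values).

    Returns
    -------
    (ExpressionMatrix, DataFrame)
        Prepared matrix and a provenance report with one row per
        masked entry / dropped feature (``feature, sample, action``).
    """
    arr = raw_rpm.to_numpy(dtype=float)
    neg = np.nan_to_num(arr, nan=0.0) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative RPM at sample {raw_rpm.index[i]!r}, feature {raw_rpm.columns[j]!r}"
        )

    values = np.log2(arr + 1.0)
    report: list[dict] = []

    # drop features absent (RPM == 0) in more than max_absent samples
    absent_counts = (arr == 0).sum(axis=0)
    keep = absent_counts <= max_absent
    for j in np.flatnonzero(~keep):
        report.append(
            {
                "feature": raw_rpm.columns[j],
                "sample": "",
                "action": "dropped_absent",
                "detail": f"absent in {absent_counts[j]} samples",
            }
        )

    # single-pass outlier masking per feature
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    outlier = np.abs(values - mean) > sd_limit * np.where(sd > 0, sd, np.inf)
    outlier &= ~np.isnan(values)
    for i, j in np.argwhere(outlier):
        if keep[j]:
            report.append(
                {
                    "feature": raw_rpm.columns[j],
                    "sample": raw_rpm.index[i],
                    "action": "masked_outlier",
                    "detail": f"value {values[i, j]:.4f} beyond {sd_limit} SD",
                }
            )
    values[outlier] = np.nan

    out = pd.DataFrame(values[:, keep], index=raw_rpm.index, columns=raw_rpm.columns[keep])
    kept_coords = None
    if coords is not None:
        kept_coords = coords.loc[[f for f in out.columns if f in coords.index]]
    return (
        ExpressionMatrix(out, kept_coords),
        pd.DataFrame(report, columns=["feature", "sample", "action", "detail"]),
    )


def categorize_cnv(segment_value, threshold: float = 0.3):
    """Categorize a log2 copy-ratio into loss (-1), neutral (0) or gain (+1).

    Gain if value > threshold, loss if value < -threshold, else neutral.
    Accepts scalars or arrays.
    """
    v = np.asarray(segment_value, dtype=float)
    if np.isnan(v).any() or np.isinf(v).any():
        raise ValueError("segment value must be finite")
    out = np.where(v > threshold, 1, np.where(v < -threshold, -1, 0))
    return int(out) if np.isscalar(segment_value) else out


def categorize_methylation(
    probe_betas, cutpoints: tuple[float, ...] = (0.25, 0.5, 0.75)
) -> int:
    """Collapse promoter-probe beta values to a 0-3 methylation ordinal.

    The mean beta over available probes is compared against the
    cutpoints; the category is the number of cutpoints strictly below
    the mean, so a mean exactly at a cutpoint falls in the lower
    category. With the default quartile cutpoints: 0.1 -> 0, 0.3 -> 1,
    0.6 -> 2, 0.9 -> 3.
    """
    betas = np.asarray(probe_betas, dtype=float)
    betas = betas[~np.isnan(betas)]
    if betas.size == 0:
        raise ValueError("no probe beta values available")
    if betas.min() < 0 or betas.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    mean = float(betas.mean())
    return int(np.searchsorted(np.asarray(cutpoints), mean, side="left"))
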