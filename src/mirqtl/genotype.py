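"""Genotype containers and imputation-quality control.

Implements the variant-level QC applied to imputed genotypes before
cis-eQTL mapping: imputation info-score, minor-allele-frequency,
per-call posterior-probability and Hardy-Weinberg filters; composite
LD r^2 on allele dosages; tag-SNP neighbourhood expansion; and
PCA-based ancestry assignment against a labelled reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "hwe_test",
    "filter_variants",
    "ld_r2",
    "expand_tag_snps",
    "assign_ancestry",
]

#: columns every variant table must carry
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "info_score")


class UndefinedLdError(ValueError):
    """LD is undefined for a constant dosage vector."""


@dataclass
class GenotypeMatrix:
    """Per-sample expected alt-allele dosages with variant metadata.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, ref, alt,
        info_score`` (1-based positions). Extra columns are preserved.
    dosages : numpy.ndarray
        ``(n_variants, n_samples)`` float array of expected alt-allele
        counts in [0, 2]; NaN marks a missing call.
    sample_ids : sequence of str
    max_posterior : numpy.ndarray, optional
        Same shape as ``dosages``; per-call maximum genotype
        probability in [0, 1] from imputation.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]
    max_posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = list(self.sample_ids)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be 1-based (>= 1)")
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_ids)} samples"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.max_posterior is not None:
            self.max_posterior = np.asarray(self.max_posterior, dtype=float)
            if self.max_posterior.shape != self.dosages.shape:
                raise ValueError("max_posterior shape must match dosages")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[idx[0]]

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency from mean dosage over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nanmean(self.dosages, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def take(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            variants=self.variants.iloc[rows].reset_index(drop=True),
            dosages=self.dosages[rows].copy(),
            sample_ids=self.sample_ids,
            max_posterior=None if self.max_posterior is None else self.max_posterior[rows].copy(),
        )


@dataclass(frozen=True)
class QcThresholds:
    """Variant-QC thresholds; all comparisons are strict (> / <)."""

    min_info: float = 0.7
    min_maf: float = 0.05
    min_posterior: float = 0.7
    min_hwe_p: float = 1e-6
    min_ld_r2: float = 0.5
    cis_window: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("min_info", "min_maf", "min_posterior"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.min_hwe_p <= 1:
            raise ValueError("min_hwe_p outside [0, 1]")
        if not 0 <= self.min_ld_r2 <= 1:
            raise ValueError("min_ld_r2 outside [0, 1]")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Parameters
    ----------
    genotype_counts : (hom-ref, het, hom-alt) counts.

    Returns
    -------
    float
        Upper-tail chi-square p-value. Monomorphic variants (either
        allele absent) carry no measurable departure and return 1.0.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count is zero")
    p_alt = (2 * n_bb + n_ab) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    expected = np.array(
        [n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2]
    )
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to best-guess genotypes (nearest integer, ties to even)."""
    return np.rint(dosages)


def hwe_p_from_dosages(dosages: np.ndarray) -> float:
    """HWE p-value from best-guess genotypes of one variant's dosages."""
    calls = _hard_calls(dosages[~np.isnan(dosages)])
    counts = (int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum()))
    if sum(counts) == 0:
        return np.nan
    return hwe_test(counts)


def filter_variants(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the four imputation-QC criteria to a genotype matrix.

    Per-sample calls with max posterior probability <= ``min_posterior``
    are set missing first; MAF and HWE are then computed on the
    remaining calls. A variant is kept iff info score > ``min_info``,
    MAF > ``min_maf`` and HWE p > ``min_hwe_p``.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        The filtered matrix (input order preserved) and a long-format
        report with one row per variant per criterion
        (``variant, criterion, value, pass``) plus per-criterion
        removal attribution in ``removed_by`` (the first failing
        criterion, in the order info, maf, hwe).
    """
    dosages = g.dosages.copy()
    masked_calls = 0
    if g.max_posterior is not None:
        low = g.max_posterior <= t.min_posterior
        masked_calls = int(np.sum(low & ~np.isnan(dosages)))
        dosages[low] = np.nan

    work = GenotypeMatrix(g.variants.copy(), dosages, g.sample_ids)
    maf = work.maf()
    hwe_p = np.array([hwe_p_from_dosages(dosages[i]) for i in range(work.n_variants)])
    info = g.variants["info_score"].to_numpy(dtype=float)

    pass_info = info > t.min_info
    pass_maf = maf > t.min_maf
    pass_hwe = hwe_p > t.min_hwe_p
    keep = pass_info & pass_maf & pass_hwe

    removed_by = np.full(work.n_variants, "", dtype=object)
    removed_by[~pass_hwe] = "hwe"
    removed_by[~pass_maf] = "maf"
    removed_by[~pass_info] = "info"

    rows = []
    for crit, values, ok in (
        ("info", info, pass_info),
        ("maf", maf, pass_maf),
        ("hwe", hwe_p, pass_hwe),
    ):
        for i, vid in enumerate(g.variants["id"]):
            rows.append(
                {
                    "variant": vid,
                    "criterion": crit,
                    "value": values[i],
                    "pass": bool(ok[i]),
                    "removed_by": removed_by[i] if not keep[i] else "",
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["masked_calls"] = masked_calls
    report.attrs["removal_counts"] = {
        crit: int((removed_by == crit).sum()) for crit in ("info", "maf", "hwe")
    }

    out = GenotypeMatrix(
        variants=g.variants.loc[keep].reset_index(drop=True),
        dosages=dosages[keep],
        sample_ids=g.sample_ids,
        max_posterior=None if g.max_posterior is None else g.max_posterior[keep].copy(),
    )
    return out, report


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of unphased dosages.

    Missing entries are dropped pairwise-complete; at least 3 complete
    pairs are required and both vectors must be non-constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("fewer than 3 pairwise-complete samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLdError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def expand_tag_snps(
    tags: list[str],
    panel: GenotypeMatrix,
    t: QcThresholds = QcThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Expand GWAS tag SNPs to their LD neighbourhood in a panel.

    For each tag (given by variant id, present in ``panel``) collect
    panel variants on the same chromosome within ``cis_window`` bp and
    with dosage r^2 > ``min_ld_r2`` to the tag; the tag itself is always
    included. The union over tags is returned sorted by (chrom, pos, id)
    so the output is invariant to tag ordering; each captured variant is
    annotated with its best source tag (highest r^2, ties broken by
    distance then tag id).

    Returns (expanded matrix, report of skipped tags).
    """
    skipped = []
    # variant -> (source_tag, r2) keeping the strongest tag
    captured: dict[int, tuple[str, float, int]] = {}
    id_to_row = {vid: i for i, vid in enumerate(panel.variants["id"])}
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()

    for tag in sorted(set(tags)):
        row = id_to_row.get(tag)
        if row is None:
            warnings.warn(f"tag SNP {tag!r} absent from panel; skipped", stacklevel=2)
            skipped.append({"tag": tag, "reason": "absent from panel"})
            continue
        tag_dos = panel.dosages[row]
        near = np.flatnonzero(
            (chrom == chrom[row]) & (np.abs(pos - pos[row]) <= t.cis_window)
        )
        for j in near:
            if j == row:
                r2, dist = 1.0, 0
            else:
                try:
                    r2 = ld_r2(tag_dos, panel.dosages[j])
                except (UndefinedLdError, ValueError):
                    continue
                if r2 <= t.min_ld_r2:
                    continue
                dist = abs(int(pos[j]) - int(pos[row]))
            prev = captured.get(j)
            # strongest tag wins: higher r2, then shorter distance, then tag id
            cand = (-r2, dist, tag)
            if prev is None or cand < (-prev[1], prev[2], prev[0]):
                captured[j] = (tag, r2, dist)

    rows = sorted(captured)
    out = panel.take(rows)
    out.variants["source_tag"] = [captured[j][0] for j in rows]
    out.variants["tag_r2"] = [captured[j][1] for j in rows]
    order = out.variants.sort_values(["chrom", "pos", "id"], kind="stable").index.to_numpy()
    out = GenotypeMatrix(
        out.variants.iloc[order].reset_index(drop=True),
        out.dosages[order],
        out.sample_ids,
        None if out.max_posterior is None else out.max_posterior[order],
    )
    return out, pd.DataFrame(skipped, columns=["tag", "reason"])


def assign_ancestry(
    cohort: GenotypeMatrix,
    reference: GenotypeMatrix,
    reference_labels: pd.Series | dict[str, str],
    n_neighbors: int = 5,
    min_shared: int = 50,
) -> pd.DataFrame:
    """Label cohort samples by ancestry via PCA onto a labelled reference.

    PCA (two components) is fitted on standardized dosages of the
    variants shared between cohort and reference, over the merged
    sample set; each cohort sample is assigned the majority population
    label of its ``n_neighbors`` nearest reference samples in PC1-PC2,
    ties broken by smallest mean distance.

    Returns a DataFrame indexed by cohort sample id with columns
    ``population, PC1, PC2``.
    """
    from sklearn.decomposition import PCA

    labels = pd.Series(reference_labels)
    missing = [s for s in reference.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"reference labels missing for samples {missing[:5]}")

    shared = [v for v in cohort.variants["id"] if v in set(reference.variants["id"])]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared variants; at least {min_shared} required"
        )
    c_idx = {v: i for i, v in enumerate(cohort.variants["id"])}
    r_idx = {v: i for i, v in enumerate(reference.variants["id"])}
    c_dos = np.stack([cohort.dosages[c_idx[v]] for v in shared])  # variants x samples
    r_dos = np.stack([reference.dosages[r_idx[v]] for v in shared])

    merged = np.concatenate([r_dos, c_dos], axis=1).T  # samples x variants
    col_mean = np.nanmean(merged, axis=0)
    inds = np.where(np.isnan(merged))
    merged[inds] = np.take(col_mean, inds[1])
    sd = merged.std(axis=0)
    keep = sd > 0
    z = (merged[:, keep] - merged[:, keep].mean(axis=0)) / merged[:, keep].std(axis=0)

    pcs = PCA(n_components=2, svd_solver="full", random_state=0).fit_transform(z)
    n_ref = reference.n_samples
    ref_pcs, cohort_pcs = pcs[:n_ref], pcs[n_ref:]
    ref_labels = labels.loc[reference.sample_ids].to_numpy()

    assigned = []
    for x in cohort_pcs:
        d = np.linalg.norm(ref_pcs - x, axis=1)
        nn = np.argsort(d, kind="stable")[:n_neighbors]
        nn_labels = ref_labels[nn]
        counts = pd.Series(nn_labels).value_counts()
        top = counts[counts == counts.max()].index
        if len(top) == 1:
            assigned.append(top[0])
        else:  # tie: smallest mean distance among tied labels
            means = {lab: d[nn][nn_labels == lab].mean() for lab in top}
            assigned.append(min(sorted(means), key=lambda k: means[k]))

    return pd.DataFrame(
        {"population": assigned, "PC1": cohort_pcs[:, 0], "PC2": cohort_pcs[:, 1]},
        index=pd.Index(cohort.sample_ids, name="sample"),
    )
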