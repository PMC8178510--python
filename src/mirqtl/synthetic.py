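"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The real study population (a TCGA-style tumor cohort with imputed
germline genotypes, small-RNA and mRNA expression, copy-number and
methylation covariates, and follow-up) is controlled access, so every
downstream stage is exercised on cohorts drawn from an explicit
forward model:

* haplotypes follow a two-state Markov chain along the chromosome
  (copy the previous allele with probability ``ld_decay``, otherwise
  draw from the variant's allele frequency), giving tunable pairwise
  LD; diploid dosages are haplotype sums;
* miRNA log2 expression is the linear cis-eQTL predictor (dosage plus
  age/sex/CNV/CpG covariates) plus Gaussian noise;
* mRNA log2 expression is the linear trans predictor driven by its
  regulating miRNA plus Gaussian noise, optionally sharing a
  confounder with the miRNA layer;
* survival times are exponential with per-sample log hazard equal to
  the configured log hazard ratios times standardized expression,
  under independent uniform censoring calibrated to a target
  censoring fraction.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` child streams, so identical
configurations give bit-identical cohorts and each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression import CovariateTable, ExpressionMatrix
from .genotype import GenotypeMatrix
from .survival import TwoByTwo

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_two_by_two",
    "write_fixture",
    "planted_cascade_config",
]

_STREAMS = (
    "allele_freq",
    "haplotypes",
    "qc_fields",
    "covariates",
    "groups",
    "mirna_noise",
    "mrna_noise",
    "confounder",
    "survival",
    "censoring",
    "candidates",
)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Effect lists use (source index, target index, effect size) tuples:
    ``cis_effects`` maps variant -> miRNA (the dosage coefficient of
    the cis-eQTL model), ``trans_effects`` maps miRNA -> mRNA (the
    slope of the IV outcome model). ``covariate_effects`` are the
    age/sex/CNV/CpG coefficients of the miRNA model, with age entering
    centred at 65 years so the baseline stays interpretable.
    ``tumor_shift`` and ``survival_loghr`` take ("mirna"|"mrna", index,
    value) entries.
    """

    n_samples: int = 227
    n_variants: int = 50
    n_mirna: int = 10
    n_mrna: int = 20
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_decay: float = 0.0
    cis_effects: tuple[tuple[int, int, float], ...] = ()
    trans_effects: tuple[tuple[int, int, float], ...] = ()
    covariate_effects: tuple[float, float, float, float] = (0.01, 0.2, 0.5, -0.3)
    noise_sd: float = 1.0
    tumor_shift: tuple[tuple[str, int, float], ...] = ()
    survival_loghr: tuple[tuple[str, int, float], ...] = ()
    seed: int = 0
    # cohort-shape stand-ins, all overridable
    baseline_mirna: float = 6.0
    baseline_mrna: float = 8.0
    tumor_fraction: float = 0.8
    confounder_sd: float = 0.0
    censoring_fraction: float = 0.3
    variant_spacing: int = 10_000
    baseline_median_survival: float = 24.0  # months

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_mirna", "n_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie within (0, 1)")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must lie in (0, 1]")
        for v, j, beta in self.cis_effects:
            if not (0 <= v < self.n_variants and 0 <= j < self.n_mirna):
                raise ValueError(f"cis effect {(v, j, beta)} references a missing feature")
        for j, k, beta in self.trans_effects:
            if not (0 <= j < self.n_mirna and 0 <= k < self.n_mrna):
                raise ValueError(f"trans effect {(j, k, beta)} references a missing feature")
        for kind, idx, val in tuple(self.tumor_shift) + tuple(self.survival_loghr):
            n = self.n_mirna if kind == "mirna" else self.n_mrna if kind == "mrna" else -1
            if n < 0 or not 0 <= idx < n:
                raise ValueError(f"effect entry {(kind, idx, val)} references a missing feature")

    def streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        return {
            name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))
        }


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth manifest."""

    genotypes: GenotypeMatrix
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    covariates: CovariateTable
    survival: pd.DataFrame  # index sample; time, event
    group_labels: pd.Series  # "tumor" / "normal"
    candidates: pd.DataFrame  # gene, integrated_score
    truth: pd.DataFrame  # kind, source, target, value
    config: SimConfig

    def __post_init__(self) -> None:
        n = self.genotypes.n_samples
        for name, ids in (
            ("mirna", self.mirna.sample_ids),
            ("mrna", self.mrna.sample_ids),
            ("covariates", self.covariates.sample_ids),
            ("survival", list(self.survival.index)),
            ("group_labels", list(self.group_labels.index)),
        ):
            if len(ids) != n:
                raise ValueError(f"{name} is not aligned to the {n} genotype samples")


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld: float) -> np.ndarray:
    """Markov-chain haplotypes: copy previous allele w.p. ``ld`` else draw fresh."""
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    for v in range(1, m):
        fresh = (rng.random(n_hap) < freqs[v]).astype(np.int8)
        copy = rng.random(n_hap) < ld
        hap[:, v] = np.where(copy, hap[:, v - 1], fresh)
    return hap


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one synthetic cohort from the forward model of ``config``."""
    rngs = config.streams()
    n, m = config.n_samples, config.n_variants
    samples = [f"S{i:04d}" for i in range(n)]

    # -- genotypes -----------------------------------------------------------
    lo, hi = config.maf_range
    freqs = rngs["allele_freq"].uniform(lo, hi, size=m)
    hap = _draw_haplotypes(rngs["haplotypes"], 2 * n, freqs, config.ld_decay)
    dosages = (hap[0::2] + hap[1::2]).T.astype(float)  # variants x samples
    qc = rngs["qc_fields"]
    variants = pd.DataFrame(
        {
            "id": [f"snp{v:04d}" for v in range(m)],
            "chrom": "1",
            "pos": 1 + np.arange(m) * config.variant_spacing,
            "ref": "A",
            "alt": "G",
            "info_score": qc.uniform(0.8, 1.0, size=m),
        }
    )
    max_posterior = qc.uniform(0.85, 1.0, size=(m, n))
    genotypes = GenotypeMatrix(variants, dosages, samples, max_posterior)

    # -- covariates ----------------------------------------------------------
    crng = rngs["covariates"]
    a, b = (30 - 65) / 8.0, (90 - 65) / 8.0
    age = pd.Series(
        stats.truncnorm.rvs(a, b, loc=65, scale=8, size=n, random_state=crng),
        index=samples, name="age",
    )
    sex = pd.Series(crng.integers(0, 2, size=n), index=samples, name="sex")
    mirna_ids = [f"mir{j:04d}" for j in range(config.n_mirna)]
    cnv = pd.DataFrame(
        crng.choice([-1, 0, 1], size=(n, config.n_mirna), p=[0.2, 0.6, 0.2]),
        index=samples, columns=mirna_ids,
    )
    cpg = pd.DataFrame(
        crng.integers(0, 4, size=(n, config.n_mirna)), index=samples, columns=mirna_ids
    )
    covariates = CovariateTable(age=age, sex=sex, cnv=cnv, cpg=cpg)

    groups = pd.Series(
        np.where(rngs["groups"].random(n) < config.tumor_fraction, "tumor", "normal"),
        index=samples, name="group",
    )
    is_tumor = (groups == "tumor").to_numpy()

    confounder = (
        rngs["confounder"].normal(0.0, config.confounder_sd, size=n)
        if config.confounder_sd > 0
        else np.zeros(n)
    )

    # -- miRNA layer (cis-eQTL forward model) --------------------------------
    b_age, b_sex, b_cnv, b_cpg = config.covariate_effects
    mirna_vals = np.full((n, config.n_mirna), config.baseline_mirna)
    mirna_vals += np.outer(age.to_numpy() - 65.0, np.full(config.n_mirna, b_age))
    mirna_vals += np.outer(sex.to_numpy(), np.full(config.n_mirna, b_sex))
    mirna_vals += b_cnv * cnv.to_numpy(dtype=float)
    mirna_vals += b_cpg * cpg.to_numpy(dtype=float)
    for v, j, beta in config.cis_effects:
        mirna_vals[:, j] += beta * dosages[v]
    for kind, idx, shift in config.tumor_shift:
        if kind == "mirna":
            mirna_vals[is_tumor, idx] += shift
    mirna_vals += confounder[:, None]
    mirna_vals += rngs["mirna_noise"].normal(0.0, config.noise_sd, size=mirna_vals.shape)
    mirna_vals = np.clip(mirna_vals, 0.0, None)  # log2(RPM+1) floor

    # miRNA coordinates: cis-regulated features sit near their variant,
    # the rest are spread along the chromosome
    cis_by_mirna = {j: v for v, j, _ in config.cis_effects}
    anchors = []
    for j in range(config.n_mirna):
        if j in cis_by_mirna:
            anchors.append(int(variants["pos"].iloc[cis_by_mirna[j]]) + 5_000)
        else:
            anchors.append(1 + j * 37_000 + 12_345)
    mirna_coords = pd.DataFrame(
        {"chrom": "1", "start": anchors, "end": [p + 80 for p in anchors], "strand": "+"},
        index=pd.Index(mirna_ids, name="feature"),
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=samples, columns=mirna_ids), mirna_coords
    )

    # -- mRNA layer (trans forward model) ------------------------------------
    mrna_ids = [f"gene{k:04d}" for k in range(config.n_mrna)]
    mrna_vals = np.full((n, config.n_mrna), config.baseline_mrna)
    for j, k, beta in config.trans_effects:
        mrna_vals[:, k] += beta * (mirna_vals[:, j] - config.baseline_mirna)
    for kind, idx, shift in config.tumor_shift:
        if kind == "mrna":
            mrna_vals[is_tumor, idx] += shift
    mrna_vals += confounder[:, None]
    mrna_vals += rngs["mrna_noise"].normal(0.0, config.noise_sd, size=mrna_vals.shape)
    mrna_vals = np.clip(mrna_vals, 0.0, None)
    mrna_coords = pd.DataFrame(
        {
            "chrom": "2",
            "start": 1 + np.arange(config.n_mrna) * 100_000,
            "end": 1 + np.arange(config.n_mrna) * 100_000 + 2_000,
            "strand": "+",
        },
        index=pd.Index(mrna_ids, name="feature"),
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_vals, index=samples, columns=mrna_ids), mrna_coords
    )

    # -- survival ------------------------------------------------------------
    loghaz = np.zeros(n)
    for kind, idx, loghr in config.survival_loghr:
        vals = mirna_vals[:, idx] if kind == "mirna" else mrna_vals[:, idx]
        sd = vals.std()
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        loghaz += loghr * z
    base_rate = np.log(2.0) / config.baseline_median_survival
    t_event = rngs["survival"].exponential(1.0, size=n) / (base_rate * np.exp(loghaz))

    def censored_fraction(c: float) -> float:
        return float(np.mean(np.minimum(t_event, c)) / c)

    if config.censoring_fraction > 0:
        c_max = optimize.brentq(
            lambda c: censored_fraction(c) - config.censoring_fraction,
            t_event.min() * 1e-3,
            t_event.max() * 1e3,
        )
        t_cens = rngs["censoring"].uniform(0.0, c_max, size=n)
        t_cens = np.maximum(t_cens, 1e-6)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample"))

    # -- candidate annotation -------------------------------------------------
    planted = {mrna_ids[k] for _, k, _ in config.trans_effects}
    scores = rngs["candidates"].uniform(0.0, 1.0, size=config.n_mrna)
    scores[[k for _, k, _ in config.trans_effects]] = 0.9
    cand = pd.DataFrame({"gene": mrna_ids, "integrated_score": scores})

    truth_rows = (
        [
            {"kind": "cis", "source": variants["id"].iloc[v], "target": mirna_ids[j], "value": b}
            for v, j, b in config.cis_effects
        ]
        + [
            {"kind": "trans", "source": mirna_ids[j], "target": mrna_ids[k], "value": b}
            for j, k, b in config.trans_effects
        ]
        + [
            {"kind": "tumor_shift", "source": kind,
             "target": (mirna_ids if kind == "mirna" else mrna_ids)[i], "value": s}
            for kind, i, s in config.tumor_shift
        ]
        + [
            {"kind": "survival_loghr", "source": kind,
             "target": (mirna_ids if kind == "mirna" else mrna_ids)[i], "value": h}
            for kind, i, h in config.survival_loghr
        ]
    )
    truth = pd.DataFrame(truth_rows, columns=["kind", "source", "target", "value"])

    return SyntheticCohort(
        genotypes=genotypes,
        mirna=mirna,
        mrna=mrna,
        covariates=covariates,
        survival=survival,
        group_labels=groups,
        candidates=cand,
        truth=truth,
        config=config,
    )


def planted_cascade_config(
    seed: int = 42,
    n_samples: int = 400,
    n_variants: int = 50,
    n_mirna: int = 10,
    n_mrna: int = 20,
) -> SimConfig:
    """Standard fixture: one eSNP -> miRNA -> mRNA cascade with LD structure.

    Variant 0 drives miRNA 0 (cis effect 1.2); miRNA 0 drives gene 0
    (trans effect 0.8); miRNA 0 is up-shifted one log2 unit in tumors
    while gene 0 carries a direct -2 tumor shift (net about -1.2 after
    the upregulated miRNA propagates through the trans effect) and a
    protective hazard (log HR = log 0.5). Everything else is null, so
    the planted gene is the expected sole funnel survivor.
    """
    return SimConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        n_mirna=n_mirna,
        n_mrna=n_mrna,
        ld_decay=0.5,
        cis_effects=((0, 0, 1.2),),
        trans_effects=((0, 0, 0.8),),
        tumor_shift=(("mrna", 0, -2.0), ("mirna", 0, 1.0)),
        survival_loghr=(("mrna", 0, float(np.log(0.5))),),
        seed=seed,
    )


def generate_two_by_two(
    p_exposed_case: float,
    p_exposed_control: float,
    n_case: int,
    n_control: int,
    seed: int,
) -> TwoByTwo:
    """Binomially sampled 2x2 table with fixed case/control margins."""
    for name, p in (("p_exposed_case", p_exposed_case), ("p_exposed_control", p_exposed_control)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("margins must be positive")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_case, p_exposed_case))
    c = int(rng.binomial(n_control, p_exposed_control))
    return TwoByTwo(
        a=a, b=n_case - a, c=c, d=n_control - c,
        row_labels=("case", "control"), col_labels=("exposed", "unexposed"),
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> pd.DataFrame:
    """Serialize a cohort to the standard on-disk formats.

    Writes genotypes as VCF; miRNA expression as an RPM matrix (the
    inverse log2(RPM+1) transform, so the preparation stage is
    exercised on read-back); mRNA as a log2 matrix; feature coordinates
    as GFF3; covariates, CNV/CpG categories, survival, group labels,
    candidate scores and the truth manifest as TSV. Returns (and
    writes) a manifest listing every file with its SHA-256 checksum.
    """
    from . import io as mio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mio.write_vcf(cohort.genotypes, directory / "genotypes.vcf")
    rpm = np.power(2.0, cohort.mirna.values) - 1.0
    mio.write_expression_tsv(rpm, directory / "mirna_rpm.tsv")
    mio.write_expression_tsv(cohort.mrna.values, directory / "mrna_log2.tsv")
    coords = pd.concat([cohort.mirna.coords, cohort.mrna.coords])
    mio.write_gff3(coords, directory / "features.gff3")
    pd.DataFrame(
        {"age": cohort.covariates.age, "sex": cohort.covariates.sex}
    ).to_csv(directory / "covariates.tsv", sep="\t", index_label="sample", float_format="%.6f")
    cohort.covariates.cnv.to_csv(directory / "cnv.tsv", sep="\t", index_label="sample")
    cohort.covariates.cpg.to_csv(directory / "cpg.tsv", sep="\t", index_label="sample")
    cohort.survival.to_csv(directory / "survival.tsv", sep="\t", float_format="%.6f")
    cohort.group_labels.rename_axis("sample").to_frame().to_csv(
        directory / "groups.tsv", sep="\t"
    )
    cohort.candidates.to_csv(
        directory / "candidates.tsv", sep="\t", index=False, float_format="%.6f"
    )
    cohort.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)

    files = sorted(p.name for p in directory.iterdir() if p.name != "manifest.tsv")
    manifest = pd.DataFrame(
        {
            "file": files,
            "sha256": [mio.sha256_of(directory / f) for f in files],
            "n_bytes": [(directory / f).stat().st_size for f in files],
        }
    )
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest
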