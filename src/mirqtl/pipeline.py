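"""End-to-end orchestration: QC -> prep -> cis-eQTL -> DE -> MR -> survival -> funnel.

Each stage reads its inputs from disk and writes a TSV report to the
output directory, so stages are independently re-runnable from the
standard formats; a deterministic manifest of output checksums is
written last. Timestamps go to the run log only, never into result
files, so re-running an identical configuration reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .eqtl import scan_cis
from .expression import ExpressionMatrix, prepare_expression
from .genotype import QcThresholds, filter_variants
from .mr import FunnelThresholds, iv_scan, run_funnel
from .survival import differential_test, survival_screen

__all__ = ["PipelineConfig", "PipelineValidationError", "StageError", "run_pipeline"]

logger = logging.getLogger("mirqtl")

STAGE_ORDER = ("qc", "prep", "eqtl", "de", "mr", "survival", "funnel")

INPUT_FILES = {
    "genotypes": "genotypes.vcf",
    "mirna_rpm": "mirna_rpm.tsv",
    "mrna_log2": "mrna_log2.tsv",
    "features": "features.gff3",
    "covariates": "covariates.tsv",
    "cnv": "cnv.tsv",
    "cpg": "cpg.tsv",
    "survival": "survival.tsv",
    "groups": "groups.tsv",
    "candidates": "candidates.tsv",
}


class PipelineValidationError(ValueError):
    """Configuration or input problem detected before any stage runs."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One serializable source of truth for a pipeline run."""

    input_dir: str
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    # genotype QC
    min_info: float = 0.7
    min_maf: float = 0.05
    min_posterior: float = 0.7
    min_hwe_p: float = 1e-6
    min_ld_r2: float = 0.5
    # expression preparation
    max_absent: int = 20
    sd_limit: float = 3.0
    # cis-eQTL
    window: int = 1_000_000
    eqtl_fdr: float = 0.1
    # differential expression (small-RNA stage)
    de_fc: float = 2.0
    de_fdr: float = 0.01
    group_max_absent: int = 10
    # candidate funnel
    min_score: float = 0.1
    min_present: int = 100
    mr_fdr: float = 0.05
    funnel_de_fdr: float = 0.01
    funnel_de_log2fc: float = 0.5
    survival_fdr: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            min_info=self.min_info,
            min_maf=self.min_maf,
            min_posterior=self.min_posterior,
            min_hwe_p=self.min_hwe_p,
            min_ld_r2=self.min_ld_r2,
            cis_window=self.window,
        )

    def funnel_thresholds(self) -> FunnelThresholds:
        return FunnelThresholds(
            min_score=self.min_score,
            min_present=self.min_present,
            mr_fdr=self.mr_fdr,
            de_fdr=self.funnel_de_fdr,
            de_log2fc=self.funnel_de_log2fc,
            survival_fdr=self.survival_fdr,
        )

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise PipelineValidationError(f"unknown stages {bad}")
        indir = Path(self.input_dir)
        for key, name in INPUT_FILES.items():
            p = indir / name
            if not p.is_file():
                raise PipelineValidationError(f"input {key!r} missing or unreadable: {p}")
        self.qc_thresholds()  # range checks


# ---------------------------------------------------------------------------
# stages (each reads from disk, writes TSVs)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.8g"


def _inp(cfg: PipelineConfig, key: str) -> Path:
    return Path(cfg.input_dir) / INPUT_FILES[key]


def _out(cfg: PipelineConfig, name: str) -> Path:
    return Path(cfg.out_dir) / name


def _tumor_samples(cfg: PipelineConfig) -> list[str]:
    groups = pd.read_csv(_inp(cfg, "groups"), sep="\t", index_col="sample")["group"]
    return list(groups.index[groups == "tumor"])


def stage_qc(cfg: PipelineConfig) -> dict:
    g = mio.read_vcf(_inp(cfg, "genotypes"))
    filtered, report = filter_variants(g, cfg.qc_thresholds())
    mio.write_vcf(filtered, _out(cfg, "genotypes_filtered.vcf"))
    report.to_csv(_out(cfg, "qc_report.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    logger.info("qc: %d/%d variants pass", filtered.n_variants, g.n_variants)
    return {"n_in": g.n_variants, "n_out": filtered.n_variants}


def stage_prep(cfg: PipelineConfig) -> dict:
    rpm = mio.read_expression_tsv(_inp(cfg, "mirna_rpm"))
    coords = mio.read_gff3(_inp(cfg, "features"))
    prepared, report = prepare_expression(
        rpm, max_absent=cfg.max_absent, sd_limit=cfg.sd_limit, coords=coords
    )
    mio.write_expression_tsv(prepared.values, _out(cfg, "mirna_prepared.tsv"))
    report.to_csv(_out(cfg, "prep_report.tsv"), sep="\t", index=False)
    logger.info("prep: %d/%d features kept", len(prepared.feature_ids), rpm.shape[1])
    return {"n_in": rpm.shape[1], "n_out": len(prepared.feature_ids)}


def _prepared_mirna(cfg: PipelineConfig) -> ExpressionMatrix:
    values = mio.read_expression_tsv(_out(cfg, "mirna_prepared.tsv"))
    coords = mio.read_gff3(_inp(cfg, "features"))
    return ExpressionMatrix(values, coords.loc[[f for f in values.columns if f in coords.index]])


def stage_eqtl(cfg: PipelineConfig) -> dict:
    genotypes = mio.read_vcf(_out(cfg, "genotypes_filtered.vcf"))
    mirna = _prepared_mirna(cfg)
    covariates = mio.read_covariates(_inp(cfg, "covariates"), _inp(cfg, "cnv"), _inp(cfg, "cpg"))
    tumor = [s for s in _tumor_samples(cfg) if s in set(mirna.sample_ids)]
    mirna_t = ExpressionMatrix(mirna.values.loc[tumor], mirna.coords)
    res = scan_cis(genotypes, mirna_t, covariates, window=cfg.window, fdr=cfg.eqtl_fdr)
    res.associations.to_csv(
        _out(cfg, "eqtl_associations.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    res.skipped.to_csv(_out(cfg, "eqtl_skipped.tsv"), sep="\t", index=False)
    sig = res.significant()
    logger.info("eqtl: %d pairs tested, %d significant at FDR %g",
                len(res.associations), len(sig), cfg.eqtl_fdr)
    return {"n_in": len(res.associations), "n_out": len(sig)}


def stage_de(cfg: PipelineConfig) -> dict:
    groups = pd.read_csv(_inp(cfg, "groups"), sep="\t", index_col="sample")["group"]
    mirna = _prepared_mirna(cfg)
    de_mir, excl_mir = differential_test(
        mirna, groups.loc[mirna.sample_ids],
        fc_threshold=cfg.de_fc, q_threshold=cfg.de_fdr, group_max_absent=cfg.group_max_absent,
    )
    de_mir.to_csv(_out(cfg, "de_mirna.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)

    mrna_vals = mio.read_expression_tsv(_inp(cfg, "mrna_log2"))
    de_mrna, excl_mrna = differential_test(
        mrna_vals, groups.loc[mrna_vals.index],
        fc_threshold=2.0 ** cfg.funnel_de_log2fc, q_threshold=cfg.funnel_de_fdr,
        group_max_absent=cfg.group_max_absent,
    )
    de_mrna.to_csv(_out(cfg, "de_mrna.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.concat([excl_mir, excl_mrna]).to_csv(_out(cfg, "de_excluded.tsv"), sep="\t", index=False)
    logger.info("de: %d miRNA / %d mRNA features called",
                int(de_mir["de"].sum()), int(de_mrna["de"].sum()))
    return {"n_in": len(de_mir) + len(de_mrna),
            "n_out": int(de_mir["de"].sum()) + int(de_mrna["de"].sum())}


def stage_mr(cfg: PipelineConfig) -> dict:
    assoc = pd.read_csv(_out(cfg, "eqtl_associations.tsv"), sep="\t")
    sig = assoc[assoc["q_value"] <= cfg.eqtl_fdr]
    candidates = pd.read_csv(_inp(cfg, "candidates"), sep="\t")
    genotypes = mio.read_vcf(_out(cfg, "genotypes_filtered.vcf"))
    mirna = _prepared_mirna(cfg)
    mrna_vals = mio.read_expression_tsv(_inp(cfg, "mrna_log2"))
    tumor = _tumor_samples(cfg)
    tumor_m = [s for s in tumor if s in set(mirna.sample_ids)]
    mirna_t = ExpressionMatrix(mirna.values.loc[tumor_m], mirna.coords)
    mrna_t = ExpressionMatrix(mrna_vals.loc[[s for s in tumor if s in set(mrna_vals.index)]])

    axes = pd.DataFrame(
        [
            {"snp_id": r.snp_id, "mirna_id": r.mirna_id, "mrna_id": gene}
            for r in sig.itertuples(index=False)
            for gene in candidates["gene"].astype(str)
        ],
        columns=["snp_id", "mirna_id", "mrna_id"],
    )
    results = iv_scan(genotypes, mirna_t, mrna_t, axes)
    results.to_csv(_out(cfg, "iv_results.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    logger.info("mr: %d axes over %d instruments", len(results), len(sig))
    return {"n_in": len(axes), "n_out": int(results["p_weak"].notna().sum())}


def stage_survival(cfg: PipelineConfig) -> dict:
    surv = pd.read_csv(_inp(cfg, "survival"), sep="\t", index_col="sample")
    mrna_vals = mio.read_expression_tsv(_inp(cfg, "mrna_log2"))
    tumor = [s for s in _tumor_samples(cfg) if s in set(mrna_vals.index)]
    screen = survival_screen(mrna_vals.loc[tumor], surv.loc[tumor], fdr=cfg.survival_fdr)
    screen.to_csv(_out(cfg, "survival_screen.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    logger.info("survival: %d/%d features significant",
                int(screen["significant"].sum()), len(screen))
    return {"n_in": len(screen), "n_out": int(screen["significant"].sum())}


def stage_funnel(cfg: PipelineConfig) -> dict:
    candidates = pd.read_csv(_inp(cfg, "candidates"), sep="\t")
    mrna_vals = mio.read_expression_tsv(_inp(cfg, "mrna_log2"))
    tumor = [s for s in _tumor_samples(cfg) if s in set(mrna_vals.index)]
    present = ExpressionMatrix(mrna_vals.loc[tumor]).present_calls()
    iv_results = pd.read_csv(_out(cfg, "iv_results.tsv"), sep="\t")
    de_mrna = pd.read_csv(_out(cfg, "de_mrna.tsv"), sep="\t")
    screen = pd.read_csv(_out(cfg, "survival_screen.tsv"), sep="\t")
    report = run_funnel(
        candidates, present, iv_results, de_mrna, screen, cfg.funnel_thresholds()
    )
    report.stages.to_csv(_out(cfg, "funnel_stages.tsv"), sep="\t", index=False)
    report.flags.to_csv(_out(cfg, "funnel_flags.tsv"), sep="\t")
    logger.info("funnel:\n%s", report.summary())
    return {"n_in": len(candidates), "n_out": len(report.survivors())}


_STAGE_FUNCS = {
    "qc": stage_qc,
    "prep": stage_prep,
    "eqtl": stage_eqtl,
    "de": stage_de,
    "mr": stage_mr,
    "survival": stage_survival,
    "funnel": stage_funnel,
}


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Validate, run the configured stages in fixed order, write the manifest.

    Returns the manifest DataFrame (stage counts plus per-file
    checksums of every result file).
    """
    from . import __version__

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("mirqtl %s starting; seed=%d", __version__, config.seed)

    config.to_yaml(out_dir / "config_snapshot.yaml")
    stage_counts = []
    try:
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            try:
                counts = _STAGE_FUNCS[stage](config)
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise StageError(stage, str(exc)) from exc
            stage_counts.append({"stage": stage, **counts})
    finally:
        # manifest covers result files only (never the run log or the
        # config snapshot, whose paths differ between runs); it is
        # written even on failure, as a partial manifest
        counts_df = pd.DataFrame(stage_counts, columns=["stage", "n_in", "n_out"])
        counts_df.to_csv(out_dir / "stage_counts.tsv", sep="\t", index=False)
        files = sorted(
            p.name
            for p in out_dir.iterdir()
            if p.suffix in {".tsv", ".vcf"} and p.name != "manifest.tsv"
        )
        manifest = pd.DataFrame(
            {
                "file": files,
                "sha256": [mio.sha256_of(out_dir / f) for f in files],
                "n_bytes": [(out_dir / f).stat().st_size for f in files],
            }
        )
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        logger.removeHandler(handler)
        handler.close()
    return manifest
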