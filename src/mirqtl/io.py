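"""Readers and writers for the pipeline's standard file formats.

Genotypes travel as VCF (FORMAT ``DS`` dosage, ``GP`` genotype
probabilities, INFO ``INFO`` imputation quality) through pysam, or as
Oxford GEN+SAMPLE text pairs as produced by imputation software (no
installed library reads GEN, so a minimal reader/writer lives here).
Expression matrices, covariates, survival and report tables are plain
TSV; feature coordinates are GFF3.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .expression import CovariateTable
from .genotype import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gen",
    "read_gen",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gff3",
    "read_gff3",
    "read_covariates",
    "sha256_of",
]


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _gp_from(dosage: float, posterior: float) -> tuple[float, float, float]:
    """Genotype-probability triple with the hard call at the stated posterior."""
    h = int(np.rint(dosage))
    p = [0.0, 0.0, 0.0]
    p[h] = posterior
    r = 1.0 - posterior
    if h == 1:
        p[0] = p[2] = r / 2.0
    else:
        p[1] = r
    return tuple(p)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as an uncompressed VCF with DS/GP/GT fields."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(g.variants["chrom"]):
        length = int(g.variants.loc[g.variants["chrom"] == chrom, "pos"].max()) + 1_000_000
        header.contigs.add(str(chrom), length=length)
    header.add_line(
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alt allele dosage">'
    )
    header.add_line(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">'
    )
    for s in g.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(g.n_variants):
            v = g.variants.iloc[i]
            rec = vf.new_record(
                contig=str(v["chrom"]),
                start=int(v["pos"]) - 1,
                alleles=(str(v["ref"]), str(v["alt"])),
                id=str(v["id"]),
            )
            rec.info["INFO"] = float(v["info_score"])
            for j, s in enumerate(g.sample_ids):
                d = g.dosages[i, j]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                    continue
                h = int(np.rint(d))
                rec.samples[s]["GT"] = (0, 0) if h == 0 else ((0, 1) if h == 1 else (1, 1))
                rec.samples[s]["DS"] = float(d)
                post = (
                    float(g.max_posterior[i, j]) if g.max_posterior is not None else 1.0
                )
                rec.samples[s]["GP"] = _gp_from(d, post)
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a dosage VCF (DS preferred, GT fallback) into a GenotypeMatrix."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        meta, dosages, posteriors = [], [], []
        any_gp = False
        for rec in vf:
            meta.append(
                {
                    "id": rec.id or f"{rec.contig}:{rec.pos}",
                    "chrom": rec.contig,
                    "pos": rec.pos,  # pysam .pos is 1-based
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "info_score": float(rec.info.get("INFO", 1.0)),
                }
            )
            row = np.full(len(samples), np.nan)
            prow = np.full(len(samples), np.nan)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                ds = call.get("DS")
                if ds is not None:
                    row[j] = float(ds)
                else:
                    gt = call.get("GT")
                    if gt is not None and None not in gt:
                        row[j] = float(sum(gt))
                gp = call.get("GP")
                if gp is not None and None not in gp:
                    prow[j] = float(max(gp))
                    any_gp = True
            dosages.append(row)
            posteriors.append(prow)
    return GenotypeMatrix(
        variants=pd.DataFrame(meta),
        dosages=np.array(dosages) if dosages else np.empty((0, len(samples))),
        sample_ids=samples,
        max_posterior=np.array(posteriors) if any_gp else None,
    )


# ---------------------------------------------------------------------------
# Oxford GEN + SAMPLE
# ---------------------------------------------------------------------------

def write_gen(g: GenotypeMatrix, gen_path: str | Path, sample_path: str | Path) -> None:
    """Write an Oxford GEN file plus its SAMPLE companion.

    One line per variant: ``chrom id pos ref alt`` then genotype
    probability triples per sample; missing calls are 0 0 0.
    """
    with open(gen_path, "w") as fh:
        for i in range(g.n_variants):
            v = g.variants.iloc[i]
            fields = [str(v["chrom"]), str(v["id"]), str(int(v["pos"])), str(v["ref"]), str(v["alt"])]
            for j in range(g.n_samples):
                d = g.dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0", "0"]
                else:
                    post = (
                        float(g.max_posterior[i, j]) if g.max_posterior is not None else 1.0
                    )
                    fields += [f"{p:.6f}" for p in _gp_from(d, post)]
            fh.write(" ".join(fields) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in g.sample_ids:
            fh.write(f"{s} {s} 0\n")


def read_gen(gen_path: str | Path, sample_path: str | Path) -> GenotypeMatrix:
    """Read an Oxford GEN+SAMPLE pair; dosage = p1 + 2 p2 per call."""
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh.read().splitlines() if ln.strip()]
    samples = [ln[0] for ln in lines[2:]]  # two header lines

    meta, dosages, posteriors = [], [], []
    with open(gen_path) as fh:
        for line in fh:
            parts = line.split()
            chrom, vid, pos, ref, alt = parts[:5]
            probs = np.array(parts[5:], dtype=float).reshape(-1, 3)
            if len(probs) != len(samples):
                raise ValueError(
                    f"variant {vid}: {len(probs)} genotype triples for {len(samples)} samples"
                )
            total = probs.sum(axis=1)
            row = np.where(total > 0, probs[:, 1] + 2.0 * probs[:, 2], np.nan)
            prow = np.where(total > 0, probs.max(axis=1), np.nan)
            meta.append(
                {"id": vid, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                 "info_score": 1.0}
            )
            dosages.append(row)
            posteriors.append(prow)
    return GenotypeMatrix(
        variants=pd.DataFrame(meta),
        dosages=np.array(dosages),
        sample_ids=samples,
        max_posterior=np.array(posteriors),
    )


# ---------------------------------------------------------------------------
# expression / coordinates / covariates
# ---------------------------------------------------------------------------

def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    """Samples-by-features TSV with a header row of feature ids."""
    values.to_csv(path, sep="\t", index_label="sample", float_format="%.6f")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_gff3(coords: pd.DataFrame, path: str | Path, feature_type: str = "transcript") -> None:
    """Write 1-based feature coordinates (indexed by feature id) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for fid, row in coords.iterrows():
            attrs = f"ID={fid}"
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        "mirqtl",
                        feature_type,
                        str(int(row["start"])),
                        str(int(row["end"])),
                        ".",
                        str(row.get("strand", "+")),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a coords table indexed by the ID attribute."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, _, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv).get("ID")
            rows[fid] = {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    return out


def read_covariates(
    covariates_path: str | Path, cnv_path: str | Path, cpg_path: str | Path
) -> CovariateTable:
    cov = pd.read_csv(covariates_path, sep="\t", index_col="sample")
    cnv = pd.read_csv(cnv_path, sep="\t", index_col="sample")
    cpg = pd.read_csv(cpg_path, sep="\t", index_col="sample")
    return CovariateTable(age=cov["age"], sex=cov["sex"], cnv=cnv, cpg=cpg)


def read_survival(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
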