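"""Readers and writers for the pipeline's file formats.

All tabular files are tab-separated UTF-8 with ``.`` for missing values and
no quoting; comment lines starting with ``#`` carry the run configuration
(including the RNG seed) and are skipped on read.  Genotypes are accepted
either as VCF (GT or DS fields, parsed with cyvcf2) or as a plain dosage
TSV; both yield the same :class:`~methmediate.datatypes.GenotypeMatrix`.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    CpgAnnotation,
    GenotypeMatrix,
    RunConfig,
    SampleTable,
    ValidationError,
)

log = logging.getLogger("methmediate")

_TSV_KW = dict(sep="\t", comment="#", na_values=["."], keep_default_na=False,
               float_precision="round_trip")


def _write_tsv(df: pd.DataFrame, path: str | Path,
               config: RunConfig | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        # %.17g guarantees exact float64 round trips
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample table

def read_sample_table(path: str | Path) -> SampleTable:
    """Read and validate a per-sample phenotype/covariate table."""
    df = pd.read_csv(path, **_TSV_KW)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path,
                       config: RunConfig | None = None) -> None:
    _write_tsv(samples.df, path, config)


# ---------------------------------------------------------------------------
# CpG annotation

def read_cpg_annotation(path: str | Path) -> CpgAnnotation:
    df = pd.read_csv(path, **_TSV_KW, dtype={"chr": str})
    return CpgAnnotation(df)


def write_cpg_annotation(annot: CpgAnnotation, path: str | Path,
                         config: RunConfig | None = None) -> None:
    _write_tsv(annot.df, path, config)


# ---------------------------------------------------------------------------
# beta matrix

def read_beta_matrix(path: str | Path, annot: CpgAnnotation) -> BetaMatrix:
    """Read a CpG x sample beta-value TSV, restricted to annotated CpGs.

    Missing values are imputed to the per-CpG mean across the remaining
    samples (the count imputed is logged); a value outside [0, 1] is fatal
    and names the offending cell.
    """
    df = pd.read_csv(path, **_TSV_KW, index_col=0)
    keep = [c for c in df.index if c in set(annot.cpg_ids)]
    df = df.loc[keep]
    values = df.to_numpy(float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_means, values)
        log.info("imputed %d missing beta values to per-CpG means", n_missing)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"beta value {values[i, j]} outside [0, 1] at cpg "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return BetaMatrix(list(df.index), list(df.columns), values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      config: RunConfig | None = None) -> None:
    df = beta.to_frame()
    df.index.name = "cpg"
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        df.to_csv(fh, sep="\t", na_rep=".", float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, min_maf: float = 0.01) -> GenotypeMatrix:
    """Read genotype dosages from a VCF (``.vcf``) or a dosage TSV.

    VCF records use the DS FORMAT field when present, otherwise the ALT
    allele count from GT.  Multiallelic records are skipped with a counted
    warning.  SNPs below the MAF floor are dropped (set ``min_maf=0`` to
    keep everything).
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        gm = _read_vcf(path)
    else:
        gm = _read_dosage_tsv(path)
    if min_maf > 0:
        n_before = len(gm.snp_ids)
        gm = gm.filter_maf(min_maf)
        dropped = n_before - len(gm.snp_ids)
        if dropped:
            log.info("dropped %d SNPs with MAF < %g", dropped, min_maf)
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, chrs, pos, ref, alt, rows = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:        # DS absent from the FORMAT header
            ds = None
        if ds is not None:
            dose = np.asarray(ds, float).ravel()
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                             default=np.nan)
            if np.isnan(dose).any():
                dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrs.append(str(var.CHROM))
        pos.append(int(var.POS))
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append(dose)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic VCF records")
    if not rows:
        raise ValidationError(f"no biallelic records in {path}")
    return GenotypeMatrix(snp_ids, chrs, pos, sample_ids,
                          np.vstack(rows), ref, alt)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, **_TSV_KW, dtype={"chr": str})
    meta = ["snp", "chr", "pos", "ref", "alt"]
    missing = [c for c in ("snp", "chr", "pos") if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage TSV missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        df["snp"].tolist(),
        df["chr"].astype(str).tolist(),
        df["pos"].astype(int).tolist(),
        sample_cols,
        df[sample_cols].to_numpy(float),
        df["ref"].tolist() if "ref" in df else [],
        df["alt"].tolist() if "alt" in df else [],
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path,
                        config: RunConfig | None = None) -> None:
    df = pd.DataFrame({"snp": gm.snp_ids, "chr": gm.chr, "pos": gm.pos,
                       "ref": gm.ref, "alt": gm.alt})
    dose = pd.DataFrame(gm.dosages, columns=gm.sample_ids)
    _write_tsv(pd.concat([df, dose], axis=1), path, config)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write integer dosages as a minimal VCFv4.2 with GT genotypes."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chr):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, snp in enumerate(gm.snp_ids):
            dose = gm.dosages[i]
            if not np.allclose(dose, np.round(dose)):
                raise ValidationError(
                    f"snp {snp!r} has non-integer dosages; GT output "
                    "requires hard calls"
                )
            gts = "\t".join(gt_map[int(round(d))] for d in dose)
            fh.write(f"{gm.chr[i]}\t{gm.pos[i]}\t{snp}\t{gm.ref[i]}\t"
                     f"{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# auxiliary tables

def read_external_stats(path: str | Path) -> pd.DataFrame:
    """External GWAS instrument summary stats: snp, effect_allele, beta, se, p."""
    df = pd.read_csv(path, **_TSV_KW)
    required = ["snp", "effect_allele", "beta", "se", "p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"instrument table missing columns: {missing}")
    return df


def write_external_stats(df: pd.DataFrame, path: str | Path,
                         config: RunConfig | None = None) -> None:
    _write_tsv(df, path, config)


def read_cd4_ranking(path: str | Path) -> pd.DataFrame:
    """CD4+ T-cell relevance ranking: columns cpg, score (higher = more relevant)."""
    df = pd.read_csv(path, **_TSV_KW)
    if not {"cpg", "score"} <= set(df.columns):
        raise ValidationError("cd4 ranking needs columns cpg, score")
    return df


def write_cd4_ranking(df: pd.DataFrame, path: str | Path,
                      config: RunConfig | None = None) -> None:
    _write_tsv(df, path, config)
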