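"""Two-step epigenetic Mendelian randomization.

Step 1 asks whether the exposure causally shifts each candidate CpG, using
external GWAS instruments for the exposure (their published betas as the
instrument-exposure effects) and in-sample SNP-to-CpG regressions for the
instrument-outcome effects.  Step 2 asks whether each CpG causally shifts
the severity score, instrumenting the CpG with its in-sample cis-meQTLs
(same chromosome, closed 1 Mb window, 1-based coordinates).  Both steps
combine instruments with the fixed-effect inverse-variance-weighted (IVW)
estimator; instruments are greedily LD-pruned at r^2 < 0.1 on the cohort's
own dosages, best-ranked SNP first.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from scipy.stats import t as t_dist

from .datatypes import (
    BetaMatrix,
    CELL_PROP_COLUMNS,
    CpgAnnotation,
    GenotypeMatrix,
    MR_SNP_COVARIATES,
    MR_STEP2_OUTCOME_COVARIATES,
    RunConfig,
    SampleTable,
    ValidationError,
    design_matrix,
)

log = logging.getLogger("methmediate")


@dataclass
class InstrumentSet:
    """Instrument SNPs with their exposure- and outcome-side effects."""

    snps: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    provenance: str = ""
    pruned_away: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class IvwFit:
    """Fixed-effect IVW estimate with Wald interval and p-value."""

    estimate: float
    se: float
    ci: tuple[float, float]
    p: float
    n_instruments: int
    step: str = ""


def ld_prune(
    genotypes: GenotypeMatrix,
    ranking: pd.Series | dict,
    r2_cut: float = 0.1,
) -> list[str]:
    """Greedy LD pruning: best-ranked (smallest p) first, keep a SNP only if
    its squared dosage correlation with every kept SNP stays below the cut."""
    ranking = pd.Series(ranking)
    snps = [s for s in genotypes.snp_ids if s in ranking.index]
    if not snps:
        raise ValidationError("no overlap between genotypes and ranking")
    order = sorted(snps, key=lambda s: (float(ranking[s]), s))
    rows = {s: genotypes.row(s) for s in order}
    kept: list[str] = []
    for s in order:
        g = rows[s]
        ok = True
        for t in kept:
            h = rows[t]
            if g.std() == 0 or h.std() == 0:
                continue
            r = np.corrcoef(g, h)[0, 1]
            if r * r >= r2_cut:
                ok = False
                break
        if ok:
            kept.append(s)
    return kept


def snp_assoc(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    trait: np.ndarray | str,
    covariates: list[str] | None = None,
    snps: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of a trait on dosage plus shared covariates.

    Computed by residualizing trait and dosages on the covariates once
    (Frisch-Waugh-Lovell), which reproduces the per-SNP full regressions
    exactly.  Monomorphic SNPs are flagged, not fatal.
    """
    if covariates is None:
        covariates = list(MR_SNP_COVARIATES)
    if isinstance(trait, str):
        y = samples.df[trait].to_numpy(float)
    else:
        y = np.asarray(trait, float)
    if np.ptp(y) == 0:
        raise ValidationError("trait is constant")
    gm = genotypes if snps is None else genotypes.subset_snps(snps)
    order = {s: j for j, s in enumerate(gm.sample_ids)}
    cols = [order[s] for s in samples.df["sample_id"]]
    D = gm.dosages[:, cols]                       # snps x n

    C, _ = design_matrix(samples, covariates)
    n, k = C.shape
    Q, _ = np.linalg.qr(C)
    y_t = y - Q @ (Q.T @ y)
    D_t = D - (D @ Q) @ Q.T
    gg = np.einsum("ij,ij->i", D_t, D_t)
    mono = gg <= 1e-12
    gg_safe = np.where(mono, 1.0, gg)
    beta = (D_t @ y_t) / gg_safe
    dof = n - k - 1
    rss = y_t @ y_t - beta ** 2 * gg_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / dof / gg_safe)
        tval = beta / se
    p = 2 * t_dist.sf(np.abs(tval), dof)
    out = pd.DataFrame({
        "snp": gm.snp_ids, "beta": beta, "se": se, "t": tval, "p": p,
        "monomorphic": mono,
    })
    out.loc[out["monomorphic"], ["beta", "se", "t"]] = np.nan
    out.loc[out["monomorphic"], "p"] = 1.0
    return out


def cis_meqtl_scan(
    genotypes: GenotypeMatrix,
    beta: BetaMatrix,
    annot: CpgAnnotation,
    samples: SampleTable,
    cpg: str,
    window_bp: int = 1_000_000,
    p_cut: float = 0.01,
    r2_cut: float = 0.1,
    covariates: list[str] | None = None,
) -> InstrumentSet:
    """cis-meQTL instruments for one CpG: same chromosome, |distance| <=
    window (closed interval), association p < cut, then LD-pruned."""
    chrom, pos = annot.locus(cpg)
    in_cis = [
        s for s, c, p in zip(genotypes.snp_ids, genotypes.chr, genotypes.pos)
        if str(c) == str(chrom) and abs(p - pos) <= window_bp
    ]
    empty = InstrumentSet([], np.array([]), np.array([]), np.array([]),
                          np.array([]), provenance="cis_meqtl")
    if not in_cis:
        return empty
    assoc = snp_assoc(genotypes, samples, beta.row(cpg), covariates,
                      snps=in_cis)
    hits = assoc.loc[(assoc["p"] < p_cut) & ~assoc["monomorphic"]]
    if hits.empty:
        return empty
    ranking = hits.set_index("snp")["p"]
    kept = ld_prune(genotypes.subset_snps(hits["snp"].tolist()), ranking,
                    r2_cut)
    rows = hits.set_index("snp").loc[kept]
    return InstrumentSet(
        kept, rows["beta"].to_numpy(), rows["se"].to_numpy(),
        np.array([]), np.array([]), provenance="cis_meqtl",
        pruned_away=[s for s in hits["snp"] if s not in kept],
    )


def ivw(bx: np.ndarray, by: np.ndarray, se_by: np.ndarray,
        step: str = "") -> IvwFit:
    """Fixed-effect inverse-variance-weighted MR estimate.

    estimate = sum(bx by / se^2) / sum(bx^2 / se^2); with one instrument
    this is the Wald ratio by/bx.  Equivalent to the zero-intercept
    weighted regression of by on bx with weights 1/se^2.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_by = np.asarray(se_by, float)
    if not (len(bx) == len(by) == len(se_by)) or len(bx) == 0:
        raise ValidationError("bx, by, se_by must be equal-length, non-empty")
    if (se_by <= 0).any():
        raise ValidationError("outcome SEs must be positive")
    w = 1.0 / se_by ** 2
    denom = float(np.sum(bx ** 2 * w))
    if denom == 0:
        raise ValidationError("all instrument-exposure effects are zero")
    est = float(np.sum(bx * by * w)) / denom
    se = float(np.sqrt(1.0 / denom))
    z = est / se
    return IvwFit(
        estimate=est, se=se,
        ci=(est - 1.96 * se, est + 1.96 * se),
        p=float(2 * norm.sf(abs(z))),
        n_instruments=len(bx), step=step,
    )


def concordance(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Validation rule: a CpG is concordant when both MR steps reject.

    Expects ``step1_p`` and ``step2_p`` columns; NaN (a step that could not
    run) is never concordant.
    """
    p1 = table["step1_p"].to_numpy(float)
    p2 = table["step2_p"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        ok = (p1 < alpha) & (p2 < alpha)
    return pd.Series(np.where(np.isnan(p1) | np.isnan(p2), False, ok),
                     index=table.index, name="concordant")


def harmonize_instruments(
    external: pd.DataFrame, genotypes: GenotypeMatrix
) -> pd.DataFrame:
    """Align external effect alleles to the cohort's ALT allele.

    Rows whose effect allele matches REF get their beta sign flipped; rows
    matching neither allele are dropped with a logged count.
    """
    idx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    rows = []
    n_bad = 0
    for _, r in external.iterrows():
        i = idx.get(r["snp"])
        if i is None:
            continue
        if r["effect_allele"] == genotypes.alt[i]:
            rows.append({**r})
        elif r["effect_allele"] == genotypes.ref[i]:
            rows.append({**r, "beta": -float(r["beta"])})
        else:
            n_bad += 1
    if n_bad:
        log.warning("dropped %d instruments with unmatched alleles", n_bad)
    return pd.DataFrame(rows, columns=external.columns)


def exposure_instruments(
    external: pd.DataFrame,
    genotypes: GenotypeMatrix,
    instrument_p: float = 1e-5,
    r2_cut: float = 0.1,
) -> pd.DataFrame:
    """External exposure instruments present in the cohort, harmonized,
    filtered at the GWAS p-value threshold and LD-pruned in-sample."""
    ext = harmonize_instruments(external, genotypes)
    ext = ext.loc[ext["p"] < instrument_p]
    if ext.empty:
        return ext
    kept = ld_prune(genotypes.subset_snps(ext["snp"].tolist()),
                    ext.set_index("snp")["p"], r2_cut)
    return ext.set_index("snp").loc[kept].reset_index()


def run_two_step_mr(
    samples: SampleTable,
    beta: BetaMatrix,
    annot: CpgAnnotation,
    genotypes: GenotypeMatrix,
    candidates: list[str],
    external_stats: pd.DataFrame,
    config: RunConfig | None = None,
    outcome: str = "vacs_at_draw",
) -> pd.DataFrame:
    """Both MR steps for every candidate CpG.

    Returns one row per CpG with step-1 and step-2 IVW estimates, standard
    errors, intervals, p-values and instrument counts, plus ``concordant``
    (both steps p < 0.05).  A CpG without usable instruments in a step gets
    NaNs there and a logged warning.
    """
    config = config or RunConfig()
    ext = exposure_instruments(external_stats, genotypes,
                               config.instrument_p, config.ld_r2)
    if ext.empty:
        raise ValidationError("no usable exposure instruments")
    snp_cpg_cov = list(MR_SNP_COVARIATES)
    out_cov = list(MR_STEP2_OUTCOME_COVARIATES)

    out_assoc_cache: pd.DataFrame | None = None
    rows = []
    for cpg in candidates:
        row: dict = {"cpg": cpg}
        # step 1: exposure -> CpG
        assoc1 = snp_assoc(genotypes, samples, beta.row(cpg), snp_cpg_cov,
                           snps=ext["snp"].tolist())
        usable = ~assoc1["monomorphic"].to_numpy()
        if usable.sum() >= 1:
            fit1 = ivw(ext["beta"].to_numpy()[usable],
                       assoc1["beta"].to_numpy()[usable],
                       assoc1["se"].to_numpy()[usable], step="step1")
            row.update(step1_n_iv=fit1.n_instruments,
                       step1_estimate=fit1.estimate, step1_se=fit1.se,
                       step1_ci_lo=fit1.ci[0], step1_ci_hi=fit1.ci[1],
                       step1_p=fit1.p)
        else:
            log.warning("no usable step-1 instruments for %s", cpg)
            row.update(step1_n_iv=0, step1_estimate=np.nan, step1_se=np.nan,
                       step1_ci_lo=np.nan, step1_ci_hi=np.nan, step1_p=np.nan)
        # step 2: CpG -> outcome, cis-meQTL instruments
        inst = cis_meqtl_scan(genotypes, beta, annot, samples, cpg,
                              config.cis_window, config.meqtl_p,
                              config.ld_r2, snp_cpg_cov)
        if len(inst):
            if out_assoc_cache is None:
                out_assoc_cache = snp_assoc(genotypes, samples, outcome,
                                            out_cov).set_index("snp")
            oa = out_assoc_cache.loc[inst.snps]
            fit2 = ivw(inst.beta_exposure, oa["beta"].to_numpy(),
                       oa["se"].to_numpy(), step="step2")
            row.update(step2_n_iv=fit2.n_instruments,
                       step2_estimate=fit2.estimate, step2_se=fit2.se,
                       step2_ci_lo=fit2.ci[0], step2_ci_hi=fit2.ci[1],
                       step2_p=fit2.p)
        else:
            log.warning("no cis-meQTL instruments for %s", cpg)
            row.update(step2_n_iv=0, step2_estimate=np.nan, step2_se=np.nan,
                       step2_ci_lo=np.nan, step2_ci_hi=np.nan, step2_p=np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["concordant"] = concordance(out)
    return out


def mr_cell_proportions(
    samples: SampleTable,
    genotypes: GenotypeMatrix,
    external_stats: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict[str, IvwFit]:
    """Negative-control MR: exposure effect on each of the six cell types.

    Uses the same external instruments as MR step 1 with in-sample
    SNP-to-cell-proportion associations; a direct exposure effect on cell
    composition would confound methylation mediation, so these should be
    null.
    """
    config = config or RunConfig()
    missing = [c for c in CELL_PROP_COLUMNS if c not in samples.df.columns]
    if missing:
        raise ValidationError(f"cell proportions missing: {missing}")
    ext = exposure_instruments(external_stats, genotypes,
                               config.instrument_p, config.ld_r2)
    if ext.empty:
        raise ValidationError("no usable exposure instruments")
    fits = {}
    for col in CELL_PROP_COLUMNS:
        assoc = snp_assoc(genotypes, samples, col, list(MR_SNP_COVARIATES),
                          snps=ext["snp"].tolist())
        usable = ~assoc["monomorphic"].to_numpy()
        fits[col] = ivw(ext["beta"].to_numpy()[usable],
                        assoc["beta"].to_numpy()[usable],
                        assoc["se"].to_numpy()[usable],
                        step="cell_proportion")
    return fits
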