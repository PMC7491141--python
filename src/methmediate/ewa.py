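"""Epigenome-wide association scans and candidate-mediator selection.

Each scan regresses every CpG's beta value on a phenotype plus covariates
(sex, age, race, smoking, adherence, white-blood-cell count, five cell-type
proportions, technical negative-control PCs).  Because the design matrix is
shared across CpGs, all per-CpG ordinary-least-squares fits are computed in
one pass of linear algebra; the results are identical to looping a
single-site regression.  Candidates are CpGs below a p-value cutoff in both
an exposure scan and an outcome scan (strict inequality), optionally joined
by forced biologically motivated sites.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .datatypes import (
    BetaMatrix,
    EWA_COVARIATES,
    SampleTable,
    ValidationError,
    design_matrix,
)

#: median of the 1-df chi-square distribution
_CHI2_MEDIAN = float(chi2.ppf(0.5, df=1))


@dataclass
class EwaResult:
    """Per-CpG scan statistics plus scan metadata."""

    table: pd.DataFrame      # cpg, effect, se, t, p, constant(flag)
    phenotype: str
    covariates: list[str]
    n: int
    lam: float

    def pvalues(self) -> pd.Series:
        return self.table.set_index("cpg")["p"]


@dataclass
class CandidateSet:
    """Selected candidate mediator CpGs with their selection basis."""

    table: pd.DataFrame      # cpg, basis in {both_thresholds, forced_include}
    p_cut: float
    forced: list[str] = field(default_factory=list)

    @property
    def cpgs(self) -> list[str]:
        return self.table["cpg"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def run_ewa(
    beta: BetaMatrix,
    samples: SampleTable,
    phenotype: str,
    covariates: list[str] | None = None,
) -> EwaResult:
    """Scan every CpG: OLS of methylation on phenotype + covariates.

    ``phenotype`` is a sample-table column or ``"exposure"`` for the binary
    persistent-vs-none indicator (inconsistent reporters dropped).  Constant
    CpGs are flagged with effect 0 and p = 1 rather than failing the scan.
    """
    if covariates is None:
        covariates = list(EWA_COVARIATES)
    if phenotype == "exposure":
        pheno = samples.exposure_indicator().to_numpy(float)
    else:
        pheno = samples.df[phenotype].to_numpy(float)
    keep = ~np.isnan(pheno)
    sub = SampleTable(samples.df.loc[keep].reset_index(drop=True))
    pheno = pheno[keep]
    if np.ptp(pheno) == 0:
        raise ValidationError(f"phenotype {phenotype!r} is constant")
    cov, _ = design_matrix(sub, covariates)
    X = np.column_stack([cov, pheno])          # phenotype is the last column
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError("too few samples for the EWA design")

    order = {s: j for j, s in enumerate(beta.sample_ids)}
    cols = [order[s] for s in sub.df["sample_id"]]
    M = beta.values[:, cols].T                  # n x n_cpgs

    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ (X.T @ M)                 # k x n_cpgs
    resid = M - X @ coefs
    dof = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    effect = coefs[-1]

    constant = np.ptp(M, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, effect / se, 0.0)
    pvals = 2 * t_dist.sf(np.abs(tvals), dof)
    effect = np.where(constant, 0.0, effect)
    tvals = np.where(constant, 0.0, tvals)
    pvals = np.where(constant, 1.0, pvals)
    se = np.where(constant, np.nan, se)

    table = pd.DataFrame({
        "cpg": beta.cpg_ids,
        "effect": effect,
        "se": se,
        "t": tvals,
        "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
        "constant": constant,
    })
    lam = genomic_inflation(table.loc[~table["constant"], "p"].to_numpy())
    return EwaResult(table, phenotype, covariates, n, lam)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549.

    lambda = median(qchisq_1(1 - p)) / median(chi^2_1); a well-calibrated
    scan gives lambda near 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValidationError("no p-values for inflation factor")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / _CHI2_MEDIAN)


def cd4_pc_covariates(
    beta: BetaMatrix,
    cd4_ranking: pd.DataFrame,
    n_top: int = 1000,
    n_pcs: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the most CD4-relevant CpGs.

    Takes the ``n_top`` highest-scoring CpGs present in the matrix, centers
    each CpG, and returns the top ``n_pcs`` sample-score PCs together with
    their cumulative explained-variance fractions.  Used as covariates in
    the outcome scan so that CD4-driven CpGs (the severity score contains a
    CD4 component) do not dominate it.  Warns if the returned PCs explain
    80% of the submatrix variance or less.
    """
    present = set(beta.cpg_ids)
    ranked = [c for c in cd4_ranking.sort_values(
        "score", ascending=False, kind="stable")["cpg"] if c in present]
    if len(ranked) < n_top:
        raise ValidationError(
            f"only {len(ranked)} ranked CpGs present in the matrix; "
            f"{n_top} required"
        )
    sub = beta.subset_cpgs(ranked[:n_top]).values          # n_top x n
    centered = (sub - sub.mean(axis=1, keepdims=True)).T   # n x n_top
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    pcs = u[:, :n_pcs] * s[:n_pcs]
    cumfrac = np.cumsum(frac[:n_pcs])
    if cumfrac[-1] <= 0.80:
        warnings.warn(
            f"top {n_pcs} CD4 PCs explain only {cumfrac[-1]:.1%} of variance"
        )
    return pcs, cumfrac


def select_candidates(
    ewa_exposure: EwaResult,
    ewa_outcome: EwaResult,
    p_cut: float = 1e-3,
    forced: list[str] | None = None,
) -> CandidateSet:
    """CpGs with p strictly below the cutoff in both scans, plus forced ids."""
    forced = list(forced or [])
    px = ewa_exposure.pvalues()
    py = ewa_outcome.pvalues()
    if set(px.index) != set(py.index):
        raise ValidationError("the two scans cover different CpG universes")
    both = px.index[(px < p_cut) & (py.loc[px.index] < p_cut)].tolist()
    missing = [c for c in forced if c not in px.index]
    if missing:
        raise ValidationError(f"forced CpGs absent from scans: {missing}")
    rows = [{"cpg": c, "basis": "both_thresholds"} for c in both]
    rows += [{"cpg": c, "basis": "forced_include"}
             for c in forced if c not in both]
    return CandidateSet(pd.DataFrame(rows, columns=["cpg", "basis"]),
                        p_cut, forced)


def substance_confound_check(
    beta: BetaMatrix,
    samples: SampleTable,
    candidates: CandidateSet,
    substances: list[str] | None = None,
    covariates: list[str] | None = None,
    flag_p: float = 0.05,
) -> pd.DataFrame:
    """Association of each candidate CpG with other-substance-use measures.

    Runs the same covariate-adjusted single-site model per candidate x
    substance and flags associations with p below ``flag_p`` — candidate
    mediators tracking alcohol, cannabis or opioid use may reflect those
    exposures rather than the one under study.
    """
    if substances is None:
        substances = ["alcohol_auditc", "cannabis_freq", "opioid_freq"]
    if not len(candidates):
        return pd.DataFrame(columns=["cpg", "substance", "effect", "p", "flagged"])
    sub_beta = beta.subset_cpgs(candidates.cpgs)
    rows = []
    for substance in substances:
        scan = run_ewa(sub_beta, samples, substance, covariates)
        for _, r in scan.table.iterrows():
            rows.append({
                "cpg": r["cpg"], "substance": substance,
                "effect": r["effect"], "p": r["p"],
                "flagged": bool(r["p"] < flag_p),
            })
    return pd.DataFrame(rows)
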