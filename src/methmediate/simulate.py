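"""Synthetic-cohort generator with known mediation ground truth.

Emulates an HIV-positive observational cohort in which an exposure (ordinal
substance-use frequency, with a persistent/none/inconsistent longitudinal
grouping) shifts methylation at a small set of mediator CpGs, and those
CpGs in turn shift a continuous severity score.  The generator also plants
weak genetic instruments on the exposure liability and cis-meQTLs on the
mediator CpGs so that the two-step Mendelian-randomization stage has a
recoverable signal, and exponential survival times whose hazard increases
with exposure frequency.

Every generated effect is recorded in :class:`SimTruth` so that recovery,
coverage, and type-I-error properties of the downstream stages can be
tested against the generating parameters.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit as logit_fn
from scipy.stats import norm

from .datatypes import (
    BetaMatrix,
    CELL_TYPES,
    CpgAnnotation,
    GenotypeMatrix,
    MEDIATION_COVARIATES,
    SampleTable,
    ValidationError,
    design_matrix,
)

#: mean blood cell-mixture proportions (CD4T, CD8T, NK, B, mono, gran)
_CELL_BASE = np.array([0.15, 0.10, 0.05, 0.05, 0.08, 0.57])

#: baseline ordinal exposure-frequency distribution (codes 0..5): never
#: tried, none in last year, < monthly, 1-3/month, 1-3/week, >= 4/week
_FREQ_PROBS = np.array([0.387, 0.376, 0.085, 0.072, 0.027, 0.053])

#: longitudinal group fractions: persistent users / consistent non-users
_P_PERSISTENT = 0.303
_P_NONE = 0.231


@dataclass
class SimParams:
    """Generating parameters of the synthetic cohort.

    Exposure -> mediator effects (``beta0``) act on the logit of the beta
    value; mediator -> outcome effects (``alpha1``) act per beta-value unit
    on the severity score.  Scalars broadcast over all true mediators.
    """

    n_samples: int = 900
    n_cpgs: int = 2000
    n_true_mediators: int = 12
    alpha0: float = 0.28          # direct exposure->outcome effect
    alpha1: float | np.ndarray = -0.33   # mediator->outcome, per beta unit
    beta0: float | np.ndarray = -0.30    # exposure->mediator, logit scale
    conf_m: tuple[float, float, float] = (0.005, 0.05, 0.10)  # age/sex/smoking on logit(M)
    conf_y: tuple[float, float, float] = (0.01, 0.10, 0.20)   # age/sex/smoking on Y
    sigma_m: float = 0.45         # mediator noise SD, logit scale
    sigma_y: float = 1.0          # outcome noise SD
    module_loading: float = 0.40  # shared co-regulation factor on mediator CpGs
    dirichlet_conc: float = 60.0  # cell-mixture concentration
    n_snps: int = 150
    n_instrument_snps: int = 8
    instrument_effect: float = 0.15   # per-allele effect on exposure liability
    gwas_se: float = 0.025            # reported SE of the external instrument GWAS
    meqtl_effect: float = 0.50        # per-allele cis-meQTL effect, logit scale
    n_meqtl_per_mediator: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    hazard_coef: float = float(np.log(1.10))  # log-HR per frequency unit
    base_hazard: float = 0.03     # events per person-year at frequency 0
    censor_rate: float = 0.08     # exponential censoring rate
    admin_censor_years: float = 10.0
    n_neg_ctrl_pcs: int = 5
    cell_effect: float = 1.0      # scale of cell-mixture loadings on logit(M)
    cd4_frac: float = 0.3         # fraction of CpGs with strong CD4 loading
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_mediators > self.n_cpgs:
            raise ValidationError("n_true_mediators exceeds n_cpgs")
        if self.sigma_m <= 0 or self.sigma_y <= 0:
            raise ValidationError("noise SDs must be positive")
        lo, hi = self.maf_range
        if not (0.01 < lo < hi <= 0.5):
            raise ValidationError("maf_range must lie within (0.01, 0.5]")
        if self.n_instrument_snps > self.n_snps:
            raise ValidationError("more instrument SNPs than SNPs")

    def alpha1_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.alpha1, float),
                               (self.n_true_mediators,)).copy()

    def beta0_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta0, float),
                               (self.n_true_mediators,)).copy()


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, on the scales the analysis sees.

    ``beta0_beta_scale`` is the induced persistent-vs-none shift of each
    mediator's beta value, obtained as the average per-sample counterfactual
    difference (exposure set to 1 vs 0 with all other generated terms held
    fixed), so that the truth is directly comparable to raw-beta regression
    estimates.  ``total_effect`` = alpha0 + sum(alpha1_j * beta0_j*).
    """

    mediator_cpgs: list[str]
    alpha0: float
    alpha1: np.ndarray
    beta0_logit: np.ndarray
    beta0_beta_scale: np.ndarray
    acme: np.ndarray              # per-mediator alpha1_j * beta0_j*
    total_effect: float
    prop_mediated: float
    instrument_snps: list[str]
    meqtl_map: dict[str, list[tuple[str, float]]]
    hazard_coef: float
    nominal_maf: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cpg": self.mediator_cpgs,
            "alpha1": self.alpha1,
            "beta0_logit": self.beta0_logit,
            "beta0_beta_scale": self.beta0_beta_scale,
            "acme": self.acme,
            "total_effect": self.total_effect,
            "prop_mediated": self.prop_mediated,
        })


@dataclass
class Cohort:
    """A generated cohort: the inputs of every downstream stage plus truth."""

    samples: SampleTable
    beta: BetaMatrix
    annot: CpgAnnotation
    genotypes: GenotypeMatrix
    truth: SimTruth
    cd4_ranking: pd.DataFrame = field(default_factory=pd.DataFrame)
    external_stats: pd.DataFrame = field(default_factory=pd.DataFrame)


def _draw_covariates(n: int, params: SimParams, rng: np.random.Generator
                     ) -> pd.DataFrame:
    age = rng.normal(50.0, 8.0, n)
    sex = np.where(rng.random(n) < 0.025, "female", "male")
    race = rng.choice(["caucasian", "african_american", "other"], n,
                      p=[0.20, 0.67, 0.13])
    smoking = (rng.random(n) < 0.53).astype(int)
    adherence = (rng.random(n) < 0.78).astype(int)
    alcohol = np.clip(rng.poisson(3.0, n), 0, 12)
    cannabis = rng.choice(6, n, p=_FREQ_PROBS)
    opioid = rng.choice(6, n, p=_FREQ_PROBS)
    wbc = np.clip(rng.normal(6.5, 1.8, n), 2.0, None)
    df = pd.DataFrame({
        "age": age, "sex": sex, "race": race, "smoking": smoking,
        "adherence": adherence, "alcohol_auditc": alcohol,
        "cannabis_freq": cannabis, "opioid_freq": opioid, "wbc": wbc,
    })
    # ancestry PCs: first axis separates self-reported race groups
    race_shift = np.select([race == "african_american", race == "caucasian"],
                           [1.0, -1.0], default=0.0)
    for k in range(1, 6):
        base = race_shift if k == 1 else 0.0
        df[f"apc{k}"] = base + rng.normal(0.0, 0.5, n)
    for k in range(1, params.n_neg_ctrl_pcs + 1):
        df[f"ncpc{k}"] = rng.normal(0.0, 1.0, n)
    props = rng.dirichlet(params.dirichlet_conc * _CELL_BASE, n)
    for j, c in enumerate(CELL_TYPES):
        df[f"prop_{c}"] = props[:, j]
    return df


def _place_snps(params: SimParams, annot: pd.DataFrame,
                mediator_idx: np.ndarray, rng: np.random.Generator):
    """Assign SNP loci: instruments, cis-meQTLs near mediator CpGs, background."""
    snp_chr: list[str] = []
    snp_pos: list[int] = []
    roles: list[tuple[str, int]] = []   # (role, target mediator row or -1)
    for i in range(params.n_instrument_snps):
        snp_chr.append("7")
        snp_pos.append(int(1_000_000 + i * 5_000_000))
        roles.append(("instrument", -1))
    for row in mediator_idx:
        c, p = annot.loc[row, "chr"], int(annot.loc[row, "pos"])
        for _ in range(params.n_meqtl_per_mediator):
            snp_chr.append(str(c))
            snp_pos.append(int(p + rng.integers(-500_000, 500_001)))
            roles.append(("meqtl", int(row)))
    n_bg = params.n_snps - len(snp_chr)
    if n_bg < 0:
        raise ValidationError("n_snps too small for instruments plus meQTLs")
    for _ in range(n_bg):
        snp_chr.append(str(rng.integers(1, 23)))
        snp_pos.append(int(rng.integers(1_000_000, 200_000_000)))
        roles.append(("background", -1))
    return snp_chr, snp_pos, roles


def generate_cohort(params: SimParams) -> Cohort:
    """Generate a full synthetic cohort and its ground truth.

    The same seed yields bit-identical output.  All beta values are strictly
    inside (0, 1).
    """
    ss = np.random.SeedSequence(params.seed)
    (rng_cov, rng_geno, rng_expo, rng_meth,
     rng_out, rng_surv, rng_misc) = (np.random.default_rng(s)
                                     for s in ss.spawn(7))
    n = params.n_samples
    df = _draw_covariates(n, params, rng_cov)
    df.insert(0, "sample_id", [f"S{i:05d}" for i in range(n)])

    # ---- CpG annotation -------------------------------------------------
    cpg_ids = [f"cg{i:08d}" for i in range(params.n_cpgs)]
    annot = pd.DataFrame({
        "cpg": cpg_ids,
        "chr": rng_misc.integers(1, 23, params.n_cpgs).astype(str),
        "pos": rng_misc.integers(1_000_000, 200_000_000, params.n_cpgs),
        "gene": [f"GENE{i}" for i in range(params.n_cpgs)],
        "gene_group": rng_misc.choice(
            ["TSS200", "TSS1500", "Body", "5UTR", "3UTR"], params.n_cpgs),
        "island_relation": rng_misc.choice(
            ["Island", "N_Shore", "S_Shore", "OpenSea"], params.n_cpgs),
    })
    mediator_idx = np.arange(params.n_true_mediators)
    mediator_cpgs = [cpg_ids[i] for i in mediator_idx]

    # ---- genotypes ------------------------------------------------------
    snp_chr, snp_pos, roles = _place_snps(params, annot, mediator_idx,
                                          rng_geno)
    n_snps = len(snp_chr)
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    mafs = rng_geno.uniform(*params.maf_range, n_snps)
    dosages = rng_geno.binomial(2, mafs[:, None], (n_snps, n)).astype(float)
    genotypes = GenotypeMatrix(snp_ids, snp_chr, snp_pos,
                               df["sample_id"].tolist(), dosages)

    inst_rows = [i for i, (r, _) in enumerate(roles) if r == "instrument"]
    instrument_snps = [snp_ids[i] for i in inst_rows]
    meqtl_map: dict[str, list[tuple[str, float]]] = {c: [] for c in mediator_cpgs}
    for i, (r, target) in enumerate(roles):
        if r == "meqtl":
            meqtl_map[cpg_ids[target]].append((snp_ids[i], params.meqtl_effect))

    # ---- exposure liability -> ordinal frequency and longitudinal groups
    centered = dosages[inst_rows] - 2 * mafs[inst_rows, None]
    liability = params.instrument_effect * centered.sum(axis=0) \
        + rng_expo.normal(0.0, 1.0, n)
    cuts = np.quantile(liability, np.cumsum(_FREQ_PROBS)[:-1])
    freq = np.searchsorted(cuts, liability, side="right")
    hi = np.quantile(liability, 1.0 - _P_PERSISTENT)
    lo = np.quantile(liability, _P_NONE)
    group = np.where(liability > hi, "persistent",
                     np.where(liability < lo, "none", "inconsistent"))
    # exposure dose entering the generative models: persistent 1, none 0,
    # inconsistent 0.5 (intermittent use), so the persistent-vs-none
    # contrast equals the generating effect exactly
    x_dose = np.select([group == "persistent", group == "none"],
                       [1.0, 0.0], default=0.5)
    df["exposure_group"] = group
    df["exposure_freq"] = freq.astype(int)

    # ---- methylation ----------------------------------------------------
    alpha1 = params.alpha1_vector()
    beta0 = params.beta0_vector()
    baseline = rng_meth.normal(0.0, 0.4, params.n_cpgs)
    # cell-mixture loadings; a subset of CpGs is strongly CD4-driven
    cell_load = rng_meth.normal(0.0, 1.0, (params.n_cpgs, 6))
    cd4_mask = rng_meth.random(params.n_cpgs) < params.cd4_frac
    cell_load[cd4_mask, 0] += rng_meth.normal(0.0, 30.0, int(cd4_mask.sum()))
    cell_load *= params.cell_effect
    props = df[[f"prop_{c}" for c in CELL_TYPES]].to_numpy()
    cell_term = cell_load @ (props - _CELL_BASE).T          # n_cpgs x n
    # technical batch structure tracked by the first negative-control PC
    batch_load = rng_meth.normal(0.0, 0.05, params.n_cpgs)
    batch_term = batch_load[:, None] * df["ncpc1"].to_numpy()[None, :]
    module_factor = rng_meth.normal(0.0, 1.0, n)            # shared co-regulation
    conf_age, conf_sex, conf_smoke = params.conf_m
    conf_term = (conf_age * (df["age"].to_numpy() - 50.0)
                 + conf_sex * (df["sex"] == "female").to_numpy(float)
                 + conf_smoke * df["smoking"].to_numpy(float))
    noise = rng_meth.normal(0.0, params.sigma_m, (params.n_cpgs, n))

    logits = (baseline[:, None] + cell_term + batch_term
              + conf_term[None, :] + noise)
    for j, row in enumerate(mediator_idx):
        logits[row] += beta0[j] * x_dose + params.module_loading * module_factor
    for i, (r, target) in enumerate(roles):
        if r == "meqtl":
            logits[target] += params.meqtl_effect * (dosages[i] - 2 * mafs[i])
    betas = expit(logits)

    # induced beta-scale exposure effect: average per-sample counterfactual
    # difference at dose 1 vs 0, all other generated terms held fixed
    beta0_star = np.empty(params.n_true_mediators)
    for j, row in enumerate(mediator_idx):
        base_logit = logits[row] - beta0[j] * x_dose
        beta0_star[j] = float(np.mean(expit(base_logit + beta0[j])
                                      - expit(base_logit)))

    beta = BetaMatrix(cpg_ids, df["sample_id"].tolist(), betas)
    cd4_ranking = pd.DataFrame({"cpg": cpg_ids,
                                "score": np.abs(cell_load[:, 0])})
    cd4_ranking = cd4_ranking.sort_values("score", ascending=False,
                                          kind="stable").reset_index(drop=True)

    # ---- outcome --------------------------------------------------------
    cy_age, cy_sex, cy_smoke = params.conf_y
    predictor = (39.0 + params.alpha0 * x_dose
                 + (alpha1 @ betas[mediator_idx])
                 + cy_age * (df["age"].to_numpy() - 50.0)
                 + cy_sex * (df["sex"] == "female").to_numpy(float)
                 + cy_smoke * df["smoking"].to_numpy(float))
    df["vacs_at_draw"] = predictor + rng_out.normal(0, params.sigma_y, n)
    df["vacs_avg_after"] = predictor + rng_out.normal(0, params.sigma_y, n)

    # ---- survival -------------------------------------------------------
    rate = params.base_hazard * np.exp(params.hazard_coef * freq)
    t_event = rng_surv.exponential(1.0 / rate)
    t_censor = np.minimum(rng_surv.exponential(1.0 / params.censor_rate, n),
                          params.admin_censor_years)
    df["event"] = (t_event <= t_censor).astype(int)
    df["surv_years"] = np.maximum(np.minimum(t_event, t_censor), 1e-6)

    samples = SampleTable(df)

    # ---- external instrument GWAS summary statistics --------------------
    ext_rows = []
    for k, i in enumerate(inst_rows):
        beta_hat = params.instrument_effect \
            + rng_misc.normal(0.0, params.gwas_se)
        flip = k % 4 == 3     # some rows report the other allele
        ext_rows.append({
            "snp": snp_ids[i],
            "effect_allele": genotypes.ref[i] if flip else genotypes.alt[i],
            "beta": -beta_hat if flip else beta_hat,
            "se": params.gwas_se,
            "p": float(2 * norm.sf(abs(beta_hat) / params.gwas_se)),
        })
    # non-instrument filler rows exercising the p-value filter
    bg = [i for i, (r, _) in enumerate(roles) if r == "background"][:4]
    for i in bg:
        beta_hat = rng_misc.normal(0.0, params.gwas_se)
        ext_rows.append({
            "snp": snp_ids[i], "effect_allele": genotypes.alt[i],
            "beta": beta_hat, "se": params.gwas_se,
            "p": float(2 * norm.sf(abs(beta_hat) / params.gwas_se)),
        })
    external_stats = pd.DataFrame(ext_rows)

    acme = alpha1 * beta0_star
    total = params.alpha0 + float(acme.sum())
    truth = SimTruth(
        mediator_cpgs=mediator_cpgs,
        alpha0=params.alpha0,
        alpha1=alpha1,
        beta0_logit=beta0,
        beta0_beta_scale=beta0_star,
        acme=acme,
        total_effect=total,
        prop_mediated=float(acme.sum() / total),
        instrument_snps=instrument_snps,
        meqtl_map=meqtl_map,
        hazard_coef=params.hazard_coef,
        nominal_maf=mafs,
    )
    return Cohort(samples, beta, CpgAnnotation(annot), genotypes, truth,
                  cd4_ranking, external_stats)


def mediation_residual_scales(cohort: Cohort, cpg: str,
                              outcome: str = "vacs_avg_after"
                              ) -> tuple[float, float]:
    """Residual SDs of the mediator and outcome models for one CpG.

    Fits M ~ X + C and Y ~ X + M + C by OLS on the persistent-vs-none
    subset and returns the two residual standard deviations — the scales
    against which an injected confounder's weights are compared when
    computing the induced error correlation.
    """
    sub = cohort.samples.two_group_subset()
    keep = cohort.samples.df["exposure_group"].isin(
        ["persistent", "none"]).to_numpy()
    x = sub.exposure_indicator().to_numpy()
    cov, _ = design_matrix(sub, MEDIATION_COVARIATES)
    m = cohort.beta.row(cpg)[keep]
    y = sub.df[outcome].to_numpy(float)
    xm = np.column_stack([cov, x])
    rm = m - xm @ np.linalg.lstsq(xm, m, rcond=None)[0]
    xy = np.column_stack([cov, x, m])
    ry = y - xy @ np.linalg.lstsq(xy, y, rcond=None)[0]
    sigma_m = float(np.sqrt(rm @ rm / (len(m) - xm.shape[1])))
    sigma_y = float(np.sqrt(ry @ ry / (len(y) - xy.shape[1])))
    return sigma_m, sigma_y


def inject_unmeasured_confounder(
    cohort: Cohort,
    cpg: str,
    gamma_m: float,
    gamma_y: float,
    *,
    sigma_m: float | None = None,
    sigma_y: float | None = None,
    seed: int = 0,
) -> tuple[Cohort, float]:
    """Add a latent confounder U to one mediator and the outcome.

    U ~ N(0,1) enters the chosen CpG's beta values with weight ``gamma_m``
    and the post-draw outcome with weight ``gamma_y``, violating sequential
    ignorability.  Returns the modified cohort together with the induced
    residual correlation between the mediator- and outcome-model errors,

        rho* = gamma_m * gamma_y /
               sqrt((sigma_m^2 + gamma_m^2) * (sigma_y^2 + gamma_y^2)),

    where the residual SDs default to the pre-injection fits of the
    mediator and outcome models on the persistent/none subset.
    """
    rng = np.random.default_rng(seed)
    n = cohort.samples.n
    u = rng.normal(0.0, 1.0, n)

    if sigma_m is None or sigma_y is None:
        est_m, est_y = mediation_residual_scales(cohort, cpg)
        sigma_m = est_m if sigma_m is None else sigma_m
        sigma_y = est_y if sigma_y is None else sigma_y

    rho_star = (gamma_m * gamma_y
                / np.sqrt((sigma_m ** 2 + gamma_m ** 2)
                          * (sigma_y ** 2 + gamma_y ** 2)))

    values = cohort.beta.values.copy()
    i = cohort.beta.cpg_ids.index(cpg)
    values[i] = values[i] + gamma_m * u
    new_beta = BetaMatrix(list(cohort.beta.cpg_ids),
                          list(cohort.beta.sample_ids), values,
                          validate_range=False)
    new_df = cohort.samples.df.copy()
    new_df["vacs_avg_after"] = new_df["vacs_avg_after"].to_numpy(float) \
        + gamma_y * u
    new_cohort = dataclasses.replace(cohort, samples=SampleTable(new_df),
                                     beta=new_beta)
    return new_cohort, float(rho_star)
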