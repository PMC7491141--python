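"""Causal mediation analysis for a binary exposure and continuous outcome.

The linear structural-equation setting: a mediator model

    M_j = beta0_j X + sum_i beta_ij C_i + e2

and an outcome model

    Y = alpha0 X + sum_j alpha_j M_j + sum_i alpha_i C_i + e1

give the average causal mediation effect ACME = sum_j alpha_j beta0_j, the
average direct effect ADE = alpha0, the total effect TE = ADE + ACME, and
the proportion mediated PM = ACME / TE.  Inference is by nonparametric
bootstrap over whole samples with percentile intervals and the two-sided
sign-based p-value 2 * min(P(draw <= 0), P(draw >= 0)), floored at 1/B.

Sensitivity to unmeasured mediator-outcome confounding follows the
Imai-Keele-Yamamoto linear-SEM analysis: ACME is re-expressed as a function
of the assumed correlation rho between the mediator- and outcome-model
errors, and the rho at which ACME vanishes is the fitted residual
correlation itself (an analytic root, reported alongside its grid
rounding).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    BetaMatrix,
    MEDIATION_COVARIATES,
    SampleTable,
    ValidationError,
    design_matrix,
)


@dataclass
class MediationFit:
    """Single-mediator fit: effects, bootstrap intervals, and p-values."""

    cpg: str
    beta0: float          # exposure -> mediator
    alpha1: float         # mediator -> outcome
    acme: float
    ade: float
    te: float
    pm: float             # NaN (with pm_undefined) when TE ~ 0
    acme_ci: tuple[float, float]
    acme_p: float
    pm_ci: tuple[float, float]
    pm_p: float
    n: int
    n_boot: int
    seed: int
    pm_undefined: bool = False


@dataclass
class JointMediationFit:
    """Joint fit over several mediators sharing one outcome model."""

    cpgs: list[str]
    beta0: np.ndarray     # per-mediator exposure effects
    alpha: np.ndarray     # per-mediator outcome effects
    acme_components: np.ndarray
    acme: float
    ade: float
    te: float
    pm: float
    acme_ci: tuple[float, float]
    acme_p: float
    pm_ci: tuple[float, float]
    pm_p: float
    n: int
    n_boot: int
    seed: int
    pm_undefined: bool = False


@dataclass
class SensitivityCurve:
    """ACME as a function of the error correlation rho, with the zero crossing."""

    cpg: str
    rho: np.ndarray
    acme: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    rho_zero: float         # analytic root: the fitted residual correlation
    rho_zero_grid: float    # rho_zero rounded to the grid step
    acme_at_zero: float     # ACME(0), equals the point-estimate ACME


# ---------------------------------------------------------------------------
# internals

def _mediation_arrays(
    samples: SampleTable,
    beta: BetaMatrix,
    cpgs: list[str],
    covariates: list[str],
    outcome: str,
) -> tuple[np.ndarray, int, int]:
    """Stack [C | X | M_1..M_J | Y] on the persistent-vs-none subset."""
    x_all = samples.exposure_indicator().to_numpy(float)
    keep = ~np.isnan(x_all)
    sub = SampleTable(samples.df.loc[keep].reset_index(drop=True))
    x = x_all[keep]
    n1, n0 = int(x.sum()), int((1 - x).sum())
    if min(n0, n1) < 10:
        raise ValidationError(
            f"need >= 10 samples per exposure group, got {n1} vs {n0}"
        )
    cov, _ = design_matrix(sub, covariates)
    order = {s: j for j, s in enumerate(beta.sample_ids)}
    cols = [order[s] for s in sub.df["sample_id"]]
    M = beta.values[np.ix_([beta.cpg_ids.index(c) for c in cpgs], cols)].T
    y = sub.df[outcome].to_numpy(float)
    Z = np.column_stack([cov, x, M, y])
    k = cov.shape[1]          # covariate columns incl. intercept
    pred_out = list(range(k + 1 + len(cpgs)))
    if np.linalg.matrix_rank(Z[:, pred_out]) < len(pred_out):
        raise ValidationError(
            f"collinear mediation design for CpGs {cpgs}; "
            "check for duplicated or constant columns"
        )
    return Z, k, len(cpgs)


def _effects_from_gram(G: np.ndarray, k: int, j: int
                       ) -> tuple[np.ndarray, float, np.ndarray]:
    """(beta0 per mediator, alpha0, alpha per mediator) from Z'Z."""
    pm = list(range(k + 1))               # C, X
    po = list(range(k + 1 + j))           # C, X, M
    y_col = k + 1 + j
    beta0 = np.empty(j)
    Gpp = G[np.ix_(pm, pm)]
    for m in range(j):
        beta0[m] = np.linalg.solve(Gpp, G[pm, k + 1 + m])[-1]
    coef = np.linalg.solve(G[np.ix_(po, po)], G[po, y_col])
    return beta0, float(coef[k]), coef[k + 1:]


def _bootstrap_draws(Z: np.ndarray, k: int, j: int, B: int, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap draws of (ACME, TE); whole-sample resampling."""
    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    acme = np.empty(B)
    te = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        Zb = Z[idx]
        G = Zb.T @ Zb
        try:
            beta0, alpha0, alpha = _effects_from_gram(G, k, j)
        except np.linalg.LinAlgError:
            beta0, alpha0, alpha = _effects_from_gram(
                G + 1e-10 * np.eye(G.shape[0]), k, j)
        a = float(alpha @ beta0)
        acme[b] = a
        te[b] = alpha0 + a
    return acme, te


def _sign_p(draws: np.ndarray) -> float:
    B = len(draws)
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return max(2.0 * min(lo, hi), 1.0 / B)


def _percentile_ci(draws: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


def _pm_draws(acme: np.ndarray, te: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(np.abs(te) > 1e-12, acme / te, np.nan)
    return pm[~np.isnan(pm)]


# ---------------------------------------------------------------------------
# public operations

def fit_single_mediation(
    samples: SampleTable,
    beta: BetaMatrix,
    cpg: str,
    covariates: list[str] | None = None,
    B: int = 10_000,
    seed: int = 0,
    outcome: str = "vacs_avg_after",
) -> MediationFit:
    """Single-site mediation of the exposure-outcome effect through one CpG.

    Fits the mediator and outcome models by OLS on the persistent-vs-none
    subset and bootstraps whole samples for the ACME and
    proportion-mediated intervals.
    """
    if covariates is None:
        covariates = list(MEDIATION_COVARIATES)
    Z, k, j = _mediation_arrays(samples, beta, [cpg], covariates, outcome)
    G = Z.T @ Z
    beta0, alpha0, alpha = _effects_from_gram(G, k, j)
    acme = float(alpha[0] * beta0[0])
    te = alpha0 + acme
    pm_undefined = abs(te) <= 1e-12
    pm = math.nan if pm_undefined else acme / te

    acme_b, te_b = _bootstrap_draws(Z, k, j, B, seed)
    pm_b = _pm_draws(acme_b, te_b)
    return MediationFit(
        cpg=cpg, beta0=float(beta0[0]), alpha1=float(alpha[0]),
        acme=acme, ade=alpha0, te=te, pm=pm,
        acme_ci=_percentile_ci(acme_b), acme_p=_sign_p(acme_b),
        pm_ci=_percentile_ci(pm_b) if len(pm_b) else (math.nan, math.nan),
        pm_p=_sign_p(pm_b) if len(pm_b) else math.nan,
        n=Z.shape[0], n_boot=B, seed=seed, pm_undefined=pm_undefined,
    )


def fit_joint_mediation(
    samples: SampleTable,
    beta: BetaMatrix,
    cpgs: list[str],
    covariates: list[str] | None = None,
    B: int = 10_000,
    seed: int = 0,
    outcome: str = "vacs_avg_after",
) -> JointMediationFit:
    """Joint mediation through several CpGs sharing one outcome model.

    Per-mediator exposure effects come from separate mediator models; the
    outcome model includes all mediators at once, so correlated mediators
    split — rather than double-count — the mediated effect.
    """
    if covariates is None:
        covariates = list(MEDIATION_COVARIATES)
    Z, k, j = _mediation_arrays(samples, beta, list(cpgs), covariates, outcome)
    G = Z.T @ Z
    beta0, alpha0, alpha = _effects_from_gram(G, k, j)
    components = alpha * beta0
    acme = float(components.sum())
    te = alpha0 + acme
    pm_undefined = abs(te) <= 1e-12
    pm = math.nan if pm_undefined else acme / te

    acme_b, te_b = _bootstrap_draws(Z, k, j, B, seed)
    pm_b = _pm_draws(acme_b, te_b)
    return JointMediationFit(
        cpgs=list(cpgs), beta0=beta0, alpha=alpha,
        acme_components=components, acme=acme, ade=alpha0, te=te, pm=pm,
        acme_ci=_percentile_ci(acme_b), acme_p=_sign_p(acme_b),
        pm_ci=_percentile_ci(pm_b) if len(pm_b) else (math.nan, math.nan),
        pm_p=_sign_p(pm_b) if len(pm_b) else math.nan,
        n=Z.shape[0], n_boot=B, seed=seed, pm_undefined=pm_undefined,
    )


def derive_effect_decomposition(acme: float, total: float
                                ) -> tuple[float, float]:
    """Direct effect and proportion mediated from ACME and the total effect.

    Returns (ADE, PM) with ADE = total - ACME and PM = ACME / total; PM is
    NaN when the total effect is zero (undefined decomposition).
    """
    ade = total - acme
    if total == 0:
        return ade, math.nan
    return ade, acme / total


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m for m candidates."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def default_rho_grid(step: float = 0.05, limit: float = 0.95) -> np.ndarray:
    """Grid over the open interval (-limit, limit) at the given step."""
    k = int(round(limit / step)) - 1
    return np.round(np.arange(-k, k + 1) * step, 10)


def sensitivity_acme(
    samples: SampleTable,
    beta: BetaMatrix,
    cpg: str,
    covariates: list[str] | None = None,
    rho_grid: np.ndarray | None = None,
    B: int = 1000,
    seed: int = 0,
    outcome: str = "vacs_avg_after",
) -> SensitivityCurve:
    """Sensitivity of the ACME to violated sequential ignorability.

    In the linear SEM, with e1 the error of the outcome-on-exposure model
    (mediator excluded) and e2 the error of the mediator model,

        ACME(rho) = beta0 * (s1/s2) *
                    (r - rho * sqrt((1 - r^2) / (1 - rho^2)))

    where r = corr(e1, e2) and s1, s2 are the residual SDs.  ACME(0)
    reproduces the point-estimate ACME exactly, the curve is continuous and
    strictly decreasing (for beta0 > 0) in rho, and its unique zero is at
    rho = r.  Pointwise 95% intervals come from bootstrapping the inputs
    (beta0, s1, s2, r).
    """
    if covariates is None:
        covariates = list(MEDIATION_COVARIATES)
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, float)
    if (np.abs(rho_grid) >= 1).any():
        raise ValidationError("sensitivity grid must satisfy |rho| < 1")

    Z, k, _ = _mediation_arrays(samples, beta, [cpg], covariates, outcome)
    n = Z.shape[0]

    def curve_inputs(Zc: np.ndarray) -> tuple[float, float, float, float]:
        A = Zc[:, : k + 1]               # [C, X]
        m = Zc[:, k + 1]
        y = Zc[:, k + 2]
        coef_m, _, _, _ = np.linalg.lstsq(A, m, rcond=None)
        coef_y, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        e2 = m - A @ coef_m
        e1 = y - A @ coef_y
        s1 = float(np.sqrt(e1 @ e1))
        s2 = float(np.sqrt(e2 @ e2))
        r = float((e1 @ e2) / (s1 * s2))
        return float(coef_m[-1]), s1, s2, r

    def acme_of_rho(b0: float, s1: float, s2: float, r: float,
                    rho: np.ndarray) -> np.ndarray:
        return b0 * (s1 / s2) * (r - rho * np.sqrt((1 - r * r)
                                                   / (1 - rho * rho)))

    b0, s1, s2, r = curve_inputs(Z)
    acme_curve = acme_of_rho(b0, s1, s2, r, rho_grid)
    acme0 = float(b0 * (s1 / s2) * r)

    rng = np.random.default_rng(seed)
    boot = np.empty((B, len(rho_grid)))
    for b in range(B):
        idx = rng.integers(0, n, n)
        bb0, bs1, bs2, br = curve_inputs(Z[idx])
        boot[b] = acme_of_rho(bb0, bs1, bs2, br, rho_grid)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    step = float(rho_grid[1] - rho_grid[0]) if len(rho_grid) > 1 else 0.05
    return SensitivityCurve(
        cpg=cpg, rho=rho_grid, acme=acme_curve, ci_lo=lo, ci_hi=hi,
        rho_zero=r, rho_zero_grid=float(np.round(np.round(r / step) * step, 10)),
        acme_at_zero=acme0,
    )
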