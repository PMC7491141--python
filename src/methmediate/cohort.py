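"""Cohort-level exposure-outcome models.

Three analyses run upstream of any methylation work: an ordinary linear
regression of the severity score on exposure frequency and confounders, a
Cox proportional-hazards model of mortality on the same terms (Efron tie
handling), and a log-rank test for trend across ordered exposure-frequency
groups with equally spaced scores.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import chi2

from .datatypes import SampleTable, ValidationError, design_matrix


@dataclass
class AssociationFit:
    """Per-term estimates of a fitted association model.

    ``table`` has columns term, estimate, se, stat, p and, for proportional-
    hazards fits, hr, ci_lo, ci_hi (Wald interval exp(estimate +- 1.96 se)).
    """

    model: str
    table: pd.DataFrame
    n: int

    def term(self, name: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == name]
        if row.empty:
            raise KeyError(f"term {name!r} not in fit")
        return row.iloc[0]


def fit_linear_association(
    samples: SampleTable, outcome: str, terms: list[str]
) -> AssociationFit:
    """OLS of ``outcome`` on ``terms`` (intercept added), two-sided t tests."""
    df = samples.df
    y = df[outcome].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValidationError(f"outcome {outcome!r} is constant")
    X, names = design_matrix(samples, terms)
    if len(y) <= X.shape[1] + 2:
        raise ValidationError("too few samples for the requested terms")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, in order
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "term": names,
        "estimate": res.params,
        "se": res.bse,
        "stat": res.tvalues,
        "p": res.pvalues,
    })
    return AssociationFit("linear", table.reset_index(drop=True), len(y))


def fit_cox(
    samples: SampleTable,
    terms: list[str],
    duration: str = "surv_years",
    event: str = "event",
) -> AssociationFit:
    """Cox proportional hazards (Efron ties) with Wald HR intervals."""
    df = samples.df
    ev = df[event].to_numpy(int)
    if ev.sum() == 0:
        raise ValidationError("no events observed; cannot fit Cox model")
    if (df[duration].to_numpy(float) <= 0).any():
        raise ValidationError("survival times must be positive")
    X, names = design_matrix(samples, terms)
    data = pd.DataFrame(X[:, 1:], columns=names[1:])
    data[duration] = df[duration].to_numpy(float)
    data[event] = ev
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration, event_col=event)
    est = cph.params_
    se = cph.standard_errors_
    table = pd.DataFrame({
        "term": est.index,
        "estimate": est.to_numpy(),
        "se": se.to_numpy(),
    })
    table["stat"] = table["estimate"] / table["se"]
    table["p"] = 2 * chi2.sf(table["stat"] ** 2, df=1)
    table["hr"] = np.exp(table["estimate"])
    table["ci_lo"] = np.exp(table["estimate"] - 1.96 * table["se"])
    table["ci_hi"] = np.exp(table["estimate"] + 1.96 * table["se"])
    return AssociationFit("cox", table.reset_index(drop=True), len(data))


def km_trend_test(
    samples: SampleTable,
    group: str = "exposure_freq",
    duration: str = "surv_years",
    event: str = "event",
) -> tuple[float, float]:
    """Log-rank test for trend over ordered groups with equally spaced scores.

    Returns the 1-df chi-square statistic and its p-value.  The score
    statistic is U = sum_g s_g (O_g - E_g) with the usual multivariate
    hypergeometric variance accumulated over distinct event times.
    """
    df = samples.df
    t = df[duration].to_numpy(float)
    d = df[event].to_numpy(int)
    g = df[group].to_numpy()
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValidationError("trend test needs at least two groups")
    scores = {lev: float(i) for i, lev in enumerate(np.sort(levels))}
    s = np.array([scores[x] for x in levels])
    gi = np.searchsorted(np.sort(levels), g)

    event_times = np.unique(t[d == 1])
    u = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        dying = (t == et) & (d == 1)
        n_j = int(at_risk.sum())
        d_j = int(dying.sum())
        if n_j < 2 or d_j == 0:
            continue
        n_gj = np.bincount(gi[at_risk], minlength=len(levels)).astype(float)
        d_gj = np.bincount(gi[dying], minlength=len(levels)).astype(float)
        e_gj = d_j * n_gj / n_j
        u += float(s @ (d_gj - e_gj))
        frac = n_gj / n_j
        c = d_j * (n_j - d_j) / (n_j - 1)
        # Var(sum s_g D_g) under multivariate hypergeometric sampling
        var += c * (float(frac @ (s ** 2)) - float(frac @ s) ** 2)
    if var == 0:
        return 0.0, 1.0
    stat = u * u / var
    return float(stat), float(chi2.sf(stat, df=1))


def km_curve(
    samples: SampleTable,
    duration: str = "surv_years",
    event: str = "event",
) -> pd.DataFrame:
    """Kaplan-Meier step curve as a (time, survival) table."""
    df = samples.df.sort_values(duration)
    t = df[duration].to_numpy(float)
    d = df[event].to_numpy(int)
    times = np.unique(t[d == 1])
    surv = 1.0
    rows = [(0.0, 1.0)]
    for et in times:
        n_at_risk = int((t >= et).sum())
        d_j = int(((t == et) & (d == 1)).sum())
        surv *= 1.0 - d_j / n_at_risk
        rows.append((float(et), surv))
    return pd.DataFrame(rows, columns=["time", "survival"])
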