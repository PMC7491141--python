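"""Mediation point estimates, bootstrap inference, and rho-sensitivity."""

import numpy as np
import pytest
import statsmodels.api as sm

from methmediate import (
    SampleTable,
    SimParams,
    ValidationError,
    bonferroni_threshold,
    default_rho_grid,
    derive_effect_decomposition,
    design_matrix,
    fit_joint_mediation,
    fit_single_mediation,
    generate_cohort,
    inject_unmeasured_confounder,
    mediation_residual_scales,
    sensitivity_acme,
)
from methmediate.datatypes import MEDIATION_COVARIATES


def test_point_acme_equals_two_regression_oracle(cohort):
    cpg = cohort.truth.mediator_cpgs[0]
    fit = fit_single_mediation(cohort.samples, cohort.beta, cpg, B=10, seed=0)
    x = cohort.samples.exposure_indicator().to_numpy()
    keep = ~np.isnan(x)
    sub = SampleTable(cohort.samples.df.loc[keep].reset_index(drop=True))
    C, _ = design_matrix(sub, MEDIATION_COVARIATES)
    m = cohort.beta.row(cpg)[keep]
    y = sub.df["vacs_avg_after"].to_numpy(float)
    med = sm.OLS(m, np.column_stack([C, x[keep]])).fit()
    out = sm.OLS(y, np.column_stack([C, x[keep], m])).fit()
    assert fit.beta0 == pytest.approx(med.params[-1], abs=1e-12)
    assert fit.alpha1 == pytest.approx(out.params[-1], abs=1e-12)
    assert fit.acme == pytest.approx(out.params[-1] * med.params[-1],
                                     abs=1e-12)
    assert fit.ade == pytest.approx(out.params[-2], abs=1e-12)


def test_null_exposure_path_gives_null_acme():
    co = generate_cohort(SimParams(seed=31, n_samples=800, n_cpgs=15,
                                   n_true_mediators=1, beta0=0.0, n_snps=30))
    fit = fit_single_mediation(co.samples, co.beta, co.truth.mediator_cpgs[0],
                               B=1000, seed=1)
    assert abs(fit.acme) < 0.05
    assert fit.acme_ci[0] <= 0.0 <= fit.acme_ci[1]


def test_bootstrap_is_deterministic_given_seed(cohort):
    cpg = cohort.truth.mediator_cpgs[1]
    a = fit_single_mediation(cohort.samples, cohort.beta, cpg, B=500, seed=9)
    b = fit_single_mediation(cohort.samples, cohort.beta, cpg, B=500, seed=9)
    assert a.acme_ci == b.acme_ci and a.acme_p == b.acme_p
    c = fit_single_mediation(cohort.samples, cohort.beta, cpg, B=500, seed=10)
    assert a.acme_ci != c.acme_ci


def test_bootstrap_p_and_ci_agree(cohort):
    for cpg in cohort.truth.mediator_cpgs[:4]:
        fit = fit_single_mediation(cohort.samples, cohort.beta, cpg,
                                   B=2000, seed=3)
        excludes = fit.acme_ci[0] > 0 or fit.acme_ci[1] < 0
        if abs(fit.acme_p - 0.05) > 0.02:    # away from the boundary
            assert (fit.acme_p < 0.05) == excludes


def test_joint_with_one_mediator_reduces_to_single(cohort):
    cpg = cohort.truth.mediator_cpgs[2]
    single = fit_single_mediation(cohort.samples, cohort.beta, cpg,
                                  B=200, seed=5)
    joint = fit_joint_mediation(cohort.samples, cohort.beta, [cpg],
                                B=200, seed=5)
    assert joint.acme == pytest.approx(single.acme, abs=1e-12)
    assert joint.te == pytest.approx(single.te, abs=1e-12)
    assert joint.acme_ci == pytest.approx(single.acme_ci, abs=1e-12)


def test_joint_additive_for_independent_mediators():
    co = generate_cohort(SimParams(seed=37, n_samples=3000, n_cpgs=15,
                                   n_true_mediators=2, module_loading=0.0,
                                   n_snps=30))
    singles = [fit_single_mediation(co.samples, co.beta, c, B=200, seed=1)
               for c in co.truth.mediator_cpgs]
    joint = fit_joint_mediation(co.samples, co.beta, co.truth.mediator_cpgs,
                                B=200, seed=1)
    assert joint.acme == pytest.approx(sum(f.acme for f in singles), abs=0.02)


def test_correlated_mediators_share_joint_effect(cohort):
    """Co-regulated mediators: single-site PMs double-count, the joint PM
    must be smaller than their sum."""
    cpgs = cohort.truth.mediator_cpgs
    singles = [fit_single_mediation(cohort.samples, cohort.beta, c,
                                    B=100, seed=2) for c in cpgs[:6]]
    joint = fit_joint_mediation(cohort.samples, cohort.beta, cpgs[:6],
                                B=100, seed=2)
    assert joint.pm < sum(f.pm for f in singles)


def test_collinear_mediators_fatal(cohort):
    cpg = cohort.truth.mediator_cpgs[0]
    with pytest.raises(ValidationError, match="collinear"):
        fit_joint_mediation(cohort.samples, cohort.beta, [cpg, cpg], B=10)


def test_decomposition_worked_values():
    ade, pm = derive_effect_decomposition(0.058, 0.329)
    assert round(pm * 100, 1) == 17.6
    assert round(ade, 3) == 0.271
    _, pm = derive_effect_decomposition(0.097, 0.329)
    assert round(pm * 100, 1) == 29.5
    ade, pm = derive_effect_decomposition(0.0, 0.4)
    assert pm == 0.0 and ade == 0.4
    _, pm = derive_effect_decomposition(0.1, 0.0)
    assert np.isnan(pm)


def test_bonferroni_threshold_properties():
    assert bonferroni_threshold(0.05, 15) == pytest.approx(0.05 / 15)
    assert bonferroni_threshold(0.05, 1) == 0.05
    ts = [bonferroni_threshold(0.05, m) for m in range(1, 30)]
    assert all(a > b for a, b in zip(ts, ts[1:]))
    with pytest.raises(ValidationError):
        bonferroni_threshold(0.05, 0)


def test_sensitivity_curve_anchored_at_point_estimate(cohort):
    cpg = cohort.truth.mediator_cpgs[0]
    fit = fit_single_mediation(cohort.samples, cohort.beta, cpg, B=10, seed=0)
    curve = sensitivity_acme(cohort.samples, cohort.beta, cpg, B=50, seed=0)
    assert curve.acme_at_zero == pytest.approx(fit.acme, abs=1e-8)
    i0 = int(np.argmin(np.abs(curve.rho)))
    assert curve.acme[i0] == pytest.approx(fit.acme, abs=1e-8)


def test_sensitivity_curve_monotone_single_crossing(cohort):
    for cpg in cohort.truth.mediator_cpgs[:5]:
        fit = fit_single_mediation(cohort.samples, cohort.beta, cpg,
                                   B=10, seed=0)
        curve = sensitivity_acme(cohort.samples, cohort.beta, cpg,
                                 B=10, seed=0)
        diffs = np.diff(curve.acme)
        assert np.all(diffs < 0) or np.all(diffs > 0)
        assert np.sum(np.diff(np.sign(curve.acme)) != 0) <= 1
        # zero crossing sits at the residual correlation, sign of alpha1
        assert np.sign(curve.rho_zero) == np.sign(fit.alpha1)
        assert abs(curve.rho_zero) < 1


def test_sensitivity_grid_validation(cohort):
    cpg = cohort.truth.mediator_cpgs[0]
    with pytest.raises(ValidationError, match="rho"):
        sensitivity_acme(cohort.samples, cohort.beta, cpg,
                         rho_grid=np.array([0.0, 1.0]), B=10)
    grid = default_rho_grid()
    assert grid.min() == pytest.approx(-0.9) and grid.max() == pytest.approx(0.9)
    assert np.allclose(np.diff(grid), 0.05)


def test_sensitivity_recovers_injected_confounding():
    co = generate_cohort(SimParams(seed=21, n_samples=5000, n_cpgs=20,
                                   n_true_mediators=1, alpha1=0.0, beta0=0.0,
                                   n_snps=30))
    cpg = co.annot.cpg_ids[10]
    sm_, sy_ = mediation_residual_scales(co, cpg)
    conf, rho_star = inject_unmeasured_confounder(co, cpg, sm_, sy_, seed=4)
    assert rho_star == pytest.approx(0.5, abs=1e-9)
    curve = sensitivity_acme(conf.samples, conf.beta, cpg, B=50, seed=3)
    assert curve.rho_zero == pytest.approx(rho_star, abs=0.05)
    grid = np.round(np.arange(-0.95, 1.0, 0.05), 10)
    assert np.isclose(grid, curve.rho_zero_grid).any()


def test_small_group_precondition(cohort):
    df = cohort.samples.df.copy()
    none_rows = df.index[df.exposure_group == "none"][5:]
    df.loc[none_rows, "exposure_group"] = "inconsistent"
    with pytest.raises(ValidationError, match=">= 10"):
        fit_single_mediation(SampleTable(df), cohort.beta,
                             cohort.truth.mediator_cpgs[0], B=10)
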