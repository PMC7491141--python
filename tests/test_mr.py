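"""LD pruning, SNP associations, cis-meQTL instruments, IVW, two-step MR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from methmediate import (
    GenotypeMatrix,
    SampleTable,
    SimParams,
    ValidationError,
    cis_meqtl_scan,
    concordance,
    design_matrix,
    generate_cohort,
    ivw,
    ld_prune,
    mr_cell_proportions,
    run_two_step_mr,
    snp_assoc,
)

# ---------------------------------------------------------------------------
# LD pruning


def _random_genotypes(rng, n_snps, n, duplicate=None):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, n_snps)[:, None],
                       (n_snps, n)).astype(float)
    if duplicate:
        for a, b in duplicate:
            dos[b] = dos[a]
    return GenotypeMatrix([f"rs{i}" for i in range(n_snps)],
                          ["1"] * n_snps, list(range(100, 100 + n_snps)),
                          [f"S{i}" for i in range(n)], dos)


def test_ld_prune_keeps_better_ranked_duplicate():
    gm = _random_genotypes(np.random.default_rng(0), 4, 200,
                           duplicate=[(0, 2)])
    ranking = pd.Series({"rs0": 0.5, "rs1": 0.01, "rs2": 0.001, "rs3": 0.2})
    kept = ld_prune(gm, ranking, 0.1)
    assert "rs2" in kept and "rs0" not in kept      # rs2 outranks its copy
    assert set(kept) == {"rs1", "rs2", "rs3"}


def test_ld_prune_independent_snps_all_kept():
    gm = _random_genotypes(np.random.default_rng(1), 10, 5000)
    ranking = pd.Series({s: i * 0.01 for i, s in enumerate(gm.snp_ids)})
    assert len(ld_prune(gm, ranking, 0.1)) == 10


def _greedy_oracle(dosages, order, r2_cut):
    """Independent re-derivation: keep each SNP iff compatible with all kept."""
    kept = []
    for i in order:
        if all(np.corrcoef(dosages[i], dosages[j])[0, 1] ** 2 < r2_cut
               for j in kept):
            kept.append(i)
    return kept


def test_ld_prune_matches_bruteforce_oracle_on_20_snp_instances():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 150
        base = rng.binomial(2, rng.uniform(0.1, 0.5, 20)[:, None],
                            (20, n)).astype(float)
        # plant correlation blocks by copying with noise
        for (a, b) in [(0, 1), (2, 3), (2, 4)]:
            flip = rng.random(n) < 0.05
            base[b] = np.where(flip, 2 - base[a], base[a])
        gm = GenotypeMatrix([f"rs{i}" for i in range(20)], ["1"] * 20,
                            list(range(20)), [f"S{i}" for i in range(n)], base)
        pvals = rng.random(20)
        ranking = pd.Series(pvals, index=gm.snp_ids)
        kept = ld_prune(gm, ranking, 0.1)
        order = sorted(range(20), key=lambda i: (pvals[i], f"rs{i}"))
        expect = [f"rs{i}" for i in _greedy_oracle(base, order, 0.1)]
        assert kept == expect
        # post-hoc invariant: all pairwise r^2 below the cut
        rows = np.array([gm.row(s) for s in kept])
        r2 = np.corrcoef(rows) ** 2
        np.fill_diagonal(r2, 0.0)
        assert r2.max() < 0.1


# ---------------------------------------------------------------------------
# SNP association


def test_snp_assoc_noiseless_recovery(cohort):
    g = cohort.genotypes
    rng = np.random.default_rng(3)
    trait = 0.5 * g.dosages[4] + rng.normal(0, 1e-8, g.dosages.shape[1])
    out = snp_assoc(g, cohort.samples, trait, ["age"])
    assert out.set_index("snp").loc[g.snp_ids[4], "beta"] == pytest.approx(
        0.5, abs=1e-6)


def test_snp_assoc_matches_per_snp_ols_oracle(cohort):
    g = cohort.genotypes
    out = snp_assoc(g, cohort.samples, "vacs_at_draw")
    X, _ = design_matrix(cohort.samples,
                         ["age", "sex", "race", "ancestry_pcs"])
    y = cohort.samples.df["vacs_at_draw"].to_numpy(float)
    for i in [0, 7, 31, 59]:
        res = sm.OLS(y, np.column_stack([X, g.dosages[i]])).fit()
        assert out["beta"].iloc[i] == pytest.approx(res.params[-1], abs=1e-10)
        assert out["se"].iloc[i] == pytest.approx(res.bse[-1], abs=1e-10)
        assert out["p"].iloc[i] == pytest.approx(res.pvalues[-1], abs=1e-10)


def test_snp_assoc_null_pvalues_uniform():
    rng = np.random.default_rng(5)
    n, n_snps = 300, 5000
    co = generate_cohort(SimParams(seed=13, n_samples=n, n_cpgs=12,
                                   n_true_mediators=1, n_snps=30))
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, n_snps)[:, None],
                       (n_snps, n)).astype(float)
    gm = GenotypeMatrix([f"rs{i}" for i in range(n_snps)], ["1"] * n_snps,
                        list(range(100, 100 + n_snps)),
                        list(co.samples.df["sample_id"]), dos)
    trait = rng.normal(0, 1, n)
    out = snp_assoc(gm, co.samples, trait, ["age", "sex"])
    assert kstest(out["p"], "uniform").pvalue > 0.01


def test_snp_assoc_monomorphic_flagged(cohort):
    g = cohort.genotypes
    dos = g.dosages.copy()
    dos[2] = 1.0
    gm = GenotypeMatrix(g.snp_ids, g.chr, g.pos, g.sample_ids, dos)
    out = snp_assoc(gm, cohort.samples, "vacs_at_draw")
    row = out.iloc[2]
    assert bool(row["monomorphic"]) and np.isnan(row["beta"]) and row["p"] == 1.0


# ---------------------------------------------------------------------------
# cis-meQTL window


def test_cis_window_closed_interval_and_chromosome(cohort):
    cpg = cohort.annot.cpg_ids[0]
    chrom, pos = cohort.annot.locus(cpg)
    n = cohort.samples.n
    rng = np.random.default_rng(8)
    dos = rng.binomial(2, 0.3, (3, n)).astype(float)
    gm = GenotypeMatrix(
        ["at_edge", "outside", "other_chr"],
        [chrom, chrom, "99"],
        [pos + 1_000_000, pos + 1_000_001, pos],
        list(cohort.samples.df["sample_id"]), dos)
    inst = cis_meqtl_scan(gm, cohort.beta, cohort.annot, cohort.samples,
                          cpg, p_cut=1.0)
    considered = set(inst.snps) | set(inst.pruned_away)
    assert considered == {"at_edge"}


def test_cis_meqtl_recall_of_planted_effects():
    co = generate_cohort(SimParams(seed=23, n_samples=2000, n_cpgs=20,
                                   n_true_mediators=4, meqtl_effect=0.22,
                                   n_snps=60))
    found = planted = 0
    for cpg, pairs in co.truth.meqtl_map.items():
        inst = cis_meqtl_scan(co.genotypes, co.beta, co.annot, co.samples,
                              cpg)
        hits = set(inst.snps) | set(inst.pruned_away)
        planted += len(pairs)
        found += sum(s in hits for s, _ in pairs)
    assert found / planted >= 0.9


# ---------------------------------------------------------------------------
# IVW


def test_ivw_single_instrument_is_wald_ratio():
    fit = ivw(np.array([0.2]), np.array([0.05]), np.array([0.01]))
    assert fit.estimate == pytest.approx(0.05 / 0.2, abs=1e-12)


def test_ivw_worked_interval():
    fit = ivw(np.array([1.0]), np.array([0.206]), np.array([0.070]))
    assert round(fit.ci[0], 3) == 0.069
    assert round(fit.ci[1], 3) == 0.343
    assert fit.p == pytest.approx(3.27e-3, rel=0.05)


def test_ivw_sign_flip_invariance():
    rng = np.random.default_rng(11)
    bx, by, se = rng.normal(1, 0.2, 6), rng.normal(0.5, 0.2, 6), rng.uniform(0.05, 0.2, 6)
    flip = np.array([1, -1, 1, -1, -1, 1.0])
    a = ivw(bx, by, se)
    b = ivw(bx * flip, by * flip, se)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_ivw_degenerate_inputs():
    with pytest.raises(ValidationError):
        ivw(np.zeros(3), np.ones(3), np.ones(3))
    with pytest.raises(ValidationError):
        ivw(np.ones(2), np.ones(2), np.array([0.1, 0.0]))
    with pytest.raises(ValidationError):
        ivw(np.ones(2), np.ones(3), np.ones(3))


# ---------------------------------------------------------------------------
# two-step MR


def test_two_step_recovers_planted_chain():
    co = generate_cohort(SimParams(seed=3, n_samples=5000, n_cpgs=40,
                                   n_true_mediators=2,
                                   n_meqtl_per_mediator=6, n_snps=80))
    table = run_two_step_mr(co.samples, co.beta, co.annot, co.genotypes,
                            co.truth.mediator_cpgs + [co.annot.cpg_ids[30]],
                            co.external_stats)
    planted = table.set_index("cpg").loc[co.truth.mediator_cpgs]
    assert (planted["step1_p"] < 0.05).any()
    assert (planted["step2_p"] < 0.05).all()
    assert planted["concordant"].any()
    # the null CpG has no cis instruments at all
    null_row = table.set_index("cpg").loc[co.annot.cpg_ids[30]]
    assert null_row["step2_n_iv"] == 0 and not null_row["concordant"]


def test_step1_null_when_instruments_do_not_move_exposure():
    """GWAS-claimed instruments with no in-cohort exposure effect: the
    step-1 interval must cover zero."""
    co = generate_cohort(SimParams(seed=41, n_samples=2000, n_cpgs=20,
                                   n_true_mediators=1, instrument_effect=0.0,
                                   n_snps=40))
    idx = {s: i for i, s in enumerate(co.genotypes.snp_ids)}
    ext = pd.DataFrame({
        "snp": co.truth.instrument_snps,
        "effect_allele": [co.genotypes.alt[idx[s]]
                          for s in co.truth.instrument_snps],
        "beta": 0.15, "se": 0.025, "p": 1e-9,
    })
    table = run_two_step_mr(co.samples, co.beta, co.annot, co.genotypes,
                            co.truth.mediator_cpgs, ext)
    row = table.iloc[0]
    assert row["step1_ci_lo"] < 0 < row["step1_ci_hi"]


def test_concordance_rule_on_constructed_fifteen():
    """Both-steps intersection: 4 step-1 hits, 7 step-2 hits, 3 in common."""
    step1 = [0.003, 0.013, 0.037, 0.048] + [0.07, 0.14, 0.2, 0.22, 0.26,
                                            0.27, 0.28, 0.49, 0.65, 0.76, 0.84]
    step2 = [3.4e-6, 9.4e-3, 2.8e-4, 0.53, 3.8e-3, 3.9e-6, 0.062, 1.5e-2,
             1.4e-3, 0.62, 0.77, 0.056, 0.056, 0.23, 0.57]
    table = pd.DataFrame({"step1_p": step1, "step2_p": step2})
    assert int(concordance(table).sum()) == 3


def test_cell_proportion_mr_detects_planted_effect():
    co = generate_cohort(SimParams(seed=47, n_samples=4000, n_cpgs=12,
                                   n_true_mediators=1, n_snps=40))
    df = co.samples.df.copy()
    # exposure inflates granulocytes; renormalize so fractions stay valid
    shift = 0.035 * (df["exposure_freq"] - df["exposure_freq"].mean())
    cols = ["prop_cd4t", "prop_cd8t", "prop_nk", "prop_b", "prop_mono",
            "prop_gran"]
    df["prop_gran"] += shift
    df[cols] = df[cols].div(1.0 + shift, axis=0)
    samples = SampleTable(df)
    fits = mr_cell_proportions(samples, co.genotypes, co.external_stats)
    assert fits["prop_gran"].p < 0.05
    assert fits["prop_gran"].estimate > 0


def test_cell_proportion_mr_missing_columns_fatal(cohort):
    df = cohort.samples.df.copy()
    samples = SampleTable(df)
    samples.df = df.drop(columns=["prop_nk"])
    with pytest.raises(ValidationError, match="prop_nk"):
        mr_cell_proportions(samples, cohort.genotypes, cohort.external_stats)
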