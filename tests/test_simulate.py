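"""Generator contracts: seed determinism, LD structure, ascertainment, and
agreement of the emitted summary statistics with the generating truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import transcore as tc
from transcore.simulate import (_draw_block_genotypes, _latent_correlation,
                                simulate_gwas_cohort)


def test_seed_determinism(tiny_config):
    a = tc.simulate_reference_panel(tiny_config)
    b = tc.simulate_reference_panel(tiny_config)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    pd.testing.assert_frame_equal(a.variants, b.variants)
    arch_a = tc.generate_architecture(tiny_config)
    arch_b = tc.generate_architecture(tiny_config)
    pd.testing.assert_frame_equal(arch_a.effects, arch_b.effects)
    sa = tc.simulate_study(tiny_config, arch_a)
    sb = tc.simulate_study(tiny_config, arch_b)
    np.testing.assert_array_equal(sa.dosages, sb.dosages)
    ga = tc.compute_summary_stats(simulate_gwas_cohort(tiny_config), arch_a,
                                  tiny_config)
    gb = tc.compute_summary_stats(simulate_gwas_cohort(tiny_config), arch_b,
                                  tiny_config)
    pd.testing.assert_frame_equal(ga, gb)


def test_block_correlation_matches_target():
    # one block, two SNPs, rho=0.8: sample dosage correlation within 0.05
    rng = np.random.default_rng(11)
    a = _latent_correlation(0.3, 0.8)
    d = _draw_block_genotypes(rng, 5_000, 2, 0.3, a)
    r = np.corrcoef(d, rowvar=False)[0, 1]
    assert r == pytest.approx(0.8, abs=0.05)


def test_zero_correlation_blocks_are_independent():
    cfg = tc.SimulationConfig(seed=3, n_reference=2_000, block_correlation=0.0,
                              n_blocks=40, n_genes=6, n_core_genes=2,
                              n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    panel = tc.simulate_reference_panel(cfg)
    r = np.corrcoef(panel.dosages, rowvar=False)
    blocks = panel.variants["block_id"].to_numpy()
    within = np.abs(r[(blocks[:, None] == blocks[None, :])
                      & ~np.eye(len(blocks), dtype=bool)])
    assert within.mean() < 3 / np.sqrt(cfg.n_reference)


def test_cross_block_correlation_near_zero(tiny_config):
    panel = tc.simulate_reference_panel(tiny_config)
    r = np.corrcoef(panel.dosages, rowvar=False)
    blocks = panel.variants["block_id"].to_numpy()
    across = np.abs(r[blocks[:, None] != blocks[None, :]])
    assert across.mean() < 3 / np.sqrt(tiny_config.n_reference)


def test_allele_frequencies_within_range(tiny_config):
    panel = tc.simulate_reference_panel(tiny_config)
    freq = panel.dosages.mean(axis=0) / 2
    lo, hi = tiny_config.maf_range
    tol = 3 * np.sqrt(0.25 / (2 * tiny_config.n_reference))
    assert ((freq > lo - tol) & (freq < hi + tol)).all()
    assert not np.isnan(panel.dosages).any()


def test_study_ascertainment_exact_quotas():
    cfg = tc.SimulationConfig(seed=5, n_reference=200, n_gwas=500,
                              n_cases=100, n_controls=150, n_blocks=40,
                              n_genes=6, n_core_genes=2,
                              n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    study = tc.simulate_study(cfg, tc.generate_architecture(cfg))
    status = study.samples["status"]
    assert (status == 1).sum() == 100
    assert (status == 0).sum() == 150
    for col in ("pc1", "pc2", "pc3", "sex", "age", "hla_risk"):
        assert col in study.samples


def test_degenerate_liability_raises():
    cfg = tc.SimulationConfig(seed=5, n_cases=500, n_controls=10,
                              baseline_log_odds=-30.0, n_blocks=40,
                              n_genes=6, n_core_genes=2,
                              n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    arch = tc.generate_architecture(cfg)
    with pytest.raises(tc.SimulationError):
        tc.simulate_study(cfg, arch, max_batches=3)


def test_core_gene_true_expression_is_disease_associated(tiny_result):
    """Oracle: logistic fit of outcome on the TRUE genetic expression of a
    core gene recovers a log OR whose sign matches the liability coefficient."""
    arch = tiny_result.architecture
    genes = arch.genes.set_index("target_id")
    expr = arch.genetic_expression(tiny_result.study.dosages)
    y = tiny_result.outcome
    for target in arch.core_genes:
        g = expr[target].to_numpy()
        fit = sm.Logit(y, sm.add_constant(g / g.std(ddof=1))).fit(disp=0)
        z = fit.params[1] / fit.bse[1]
        coef = genes.loc[target, "liability_coef"]
        assert np.sign(fit.params[1]) == np.sign(coef) or abs(z) < 2


def test_null_liability_gives_uniform_association_pvalues():
    """liability_effect_sd = 0 with no HLA effect: trans-score association
    p-values are uniform (KS check at reduced replicate count)."""
    pvals = []
    for seed in range(4):
        cfg = tc.SimulationConfig(
            seed=seed, n_reference=500, n_gwas=4_000, n_cases=300,
            n_controls=300, n_blocks=40, n_genes=6, n_core_genes=2,
            n_hla_driven_genes=1, trans_eqtls_per_gene=8,
            liability_effect_sd=0.0, hla_liability_effect=0.0)
        res = tc.run_pipeline(cfg)
        pvals.extend(r.pvalue for r in res.associations if r.converged)
    assert len(pvals) >= 20
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_heritability_partition(tiny_config):
    """Trans share of generating genetic variance ~= configured fraction."""
    arch = tc.generate_architecture(tiny_config)
    maf = arch.variants["maf"].to_numpy()
    for target, grp in arch.effects.groupby("target_id"):
        v = (grp["effect"] ** 2
             * 2 * maf[grp["variant_index"]] * (1 - maf[grp["variant_index"]]))
        trans = v[grp["kind"].isin(["trans", "hla"])].sum()
        share = trans / v.sum()
        assert share == pytest.approx(
            tiny_config.trans_heritability_fraction, abs=0.1)


def test_marginal_beta_consistency_large_n():
    """With one causal SNP and no LD, the marginal estimate approaches the
    generating effect as the GWAS grows (checked at n = 20,000)."""
    cfg = tc.SimulationConfig(
        seed=9, n_gwas=20_000, n_reference=200, n_cases=50, n_controls=50,
        block_correlation=0.0, n_blocks=40, n_genes=6, n_core_genes=2,
        n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    arch = tc.generate_architecture(cfg)
    stats_df = tc.compute_summary_stats(simulate_gwas_cohort(cfg), arch, cfg)
    merged = stats_df.merge(
        arch.effects[["target_id", "variant_id", "effect"]],
        on=["target_id", "variant_id"])
    err = (merged["beta"] - merged["effect"]) / merged["se"]
    assert np.abs(err).mean() < 1.5  # standardized errors ~ N(0,1)


def test_marginal_betas_follow_ld_convolution():
    """Marginal betas agree with R @ beta_true within 3 SE on average: an LD
    partner of a causal SNP (r ~ 0.5) inherits ~ r times its effect."""
    cfg = tc.SimulationConfig(seed=13, n_gwas=20_000, n_reference=200,
                              n_cases=50, n_controls=50, n_blocks=40,
                              n_genes=6, n_core_genes=2,
                              n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    arch = tc.generate_architecture(cfg)
    gwas = simulate_gwas_cohort(cfg)
    stats_df = tc.compute_summary_stats(gwas, arch, cfg)
    variants = arch.variants
    # true marginal effect = sum over causal partners of r * beta_true
    r_all = np.corrcoef(gwas.dosages, rowvar=False)
    checked = 0
    errs = []
    for target, grp in stats_df.groupby("target_id"):
        eff = arch.effects[arch.effects["target_id"] == target]
        true_by_idx = dict(zip(eff["variant_index"], eff["effect"]))
        idx_of = dict(zip(variants["variant_id"], variants.index))
        for row in grp.itertuples():
            j = idx_of[row.variant_id]
            expected = sum(r_all[j, k] * b for k, b in true_by_idx.items()
                           if variants.loc[k, "block_id"]
                           == variants.loc[j, "block_id"])
            errs.append(abs(row.beta - expected) / row.se)
            checked += 1
    assert checked > 100
    assert np.mean(errs) < 3.0


def test_trans_records_restricted_to_tested_subset():
    cfg = tc.SimulationConfig(seed=2, n_gwas=2_000, n_reference=200,
                              n_cases=50, n_controls=50,
                              tested_snp_fraction=0.3, n_blocks=40,
                              n_genes=6, n_core_genes=2,
                              n_hla_driven_genes=1, trans_eqtls_per_gene=8)
    arch = tc.generate_architecture(cfg)
    stats_df = tc.compute_summary_stats(simulate_gwas_cohort(cfg), arch, cfg)
    # same tested subset for every gene: per-variant counts are all-or-none
    ann = arch.genes.set_index("target_id")
    n_genes = len(ann)
    counts = (stats_df.groupby("variant_id")["target_id"].nunique()
              .reindex(arch.variants["variant_id"]).fillna(0))
    # a variant absent from the tested set appears only for genes whose cis
    # window covers it (at most a couple), never for all genes in trans
    hla_ids = set(arch.variants.loc[
        arch.variants["block_id"].isin(cfg.hla_block_ids), "variant_id"])
    untested_max = counts[(counts > 0) & (counts < n_genes)].max()
    assert untested_max <= 2
    frac_full = (counts == n_genes).mean()
    # ~ tested_snp_fraction (HLA SNPs are forced into the tested set)
    assert 0.2 < frac_full < 0.45
    assert hla_ids <= set(counts[counts == n_genes].index)
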