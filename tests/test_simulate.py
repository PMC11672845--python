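"""Synthetic-cohort generator: determinism, moments, and model structure."""

import numpy as np
import pandas as pd
import pytest

from mgblup.kernels import KernelMatrix, grm_vanraden
from mgblup.phenotypes import derive_phenotypes
from mgblup.simulate import (ConfigError, SimulationConfig, simulate_asv_counts,
                             simulate_bivariate_phenotypes, simulate_cohort,
                             simulate_genotypes, simulate_growth_records,
                             simulate_phenotype)


def test_config_validation_rejects_bad_fractions():
    with pytest.raises(ConfigError):
        SimulationConfig(h2_true=0.7, m2_true=0.4)
    with pytest.raises(ConfigError):
        SimulationConfig(maf_low=0.0)
    with pytest.raises(ConfigError):
        SimulationConfig(depth_mean=-5)
    with pytest.raises(ConfigError):
        SimulationConfig(ld_rho=1.0)
    with pytest.raises(ConfigError):
        SimulationConfig(rg_true=1.5)


def test_genotypes_deterministic_under_seed():
    cfg = SimulationConfig(n_individuals=30, n_snps=50, seed=1)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    assert a.sample_ids == b.sample_ids


def test_genotypes_hwe_at_half_frequency():
    # ld_rho=0, MAF pinned at 0.5: genotype classes approach (1/4, 1/2, 1/4)
    cfg = SimulationConfig(n_individuals=4000, n_snps=50, ld_rho=0.0,
                           maf_low=0.5, maf_high=0.5, seed=2)
    g = simulate_genotypes(cfg)
    freqs = [np.mean(g.dosages == k) for k in (0, 1, 2)]
    np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)
    np.testing.assert_allclose(g.dosages.mean() / 2, 0.5, atol=0.01)


def test_genotypes_independent_markers_adjacent_r2():
    # E[r^2] between independent markers is approximately 1/n
    n = 100
    r2 = []
    for seed in range(200):
        cfg = SimulationConfig(n_individuals=n, n_snps=2, ld_rho=0.0, seed=seed)
        d = simulate_genotypes(cfg).dosages
        if d[:, 0].std() == 0 or d[:, 1].std() == 0:
            continue
        r2.append(np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2)
    assert abs(np.mean(r2) - 1.0 / n) < 3.0 * np.std(r2) / np.sqrt(len(r2))


def test_genotypes_ld_rho_induces_adjacent_correlation():
    cfg = SimulationConfig(n_individuals=400, n_snps=200, ld_rho=0.95, seed=3)
    d = simulate_genotypes(cfg).dosages
    r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2 for j in range(199)]
    # thresholding attenuates the latent correlation; still strong LD
    assert np.mean(r) > 0.3


def test_genotypes_missing_rate():
    cfg = SimulationConfig(n_individuals=200, n_snps=100, missing_rate=0.1,
                           seed=4)
    d = simulate_genotypes(cfg).dosages
    assert abs(np.isnan(d).mean() - 0.1) < 0.02


def test_asv_counts_conserve_library_sizes_and_sparsity(small_config):
    t = simulate_asv_counts(small_config)
    sizes = t.library_sizes.to_numpy()
    assert (sizes >= small_config.depth_min).all()
    # column sums are the drawn library sizes by multinomial conservation
    np.testing.assert_array_equal(t.counts.sum(axis=0).to_numpy(), sizes)
    cfg = SimulationConfig(seed=5)  # default 400 x 300 cohort
    zfrac = (simulate_asv_counts(cfg).counts.to_numpy() == 0).mean()
    assert 0.4 <= zfrac <= 0.6


def test_asv_counts_two_feature_symmetric_split():
    cfg = SimulationConfig(n_individuals=300, n_asvs=2, depth_mean=1000.0,
                           depth_sd=0.0, sparsity_target=0.0,
                           sample_lognorm_sd=0.0, seed=6)
    t = simulate_asv_counts(cfg)
    means = t.counts.mean(axis=1).to_numpy()
    # equal abundances: each ASV ~ Binomial(1000, 1/2), sd ~ 15.8
    assert abs(means[0] - 500) < 3 * 15.8 / np.sqrt(300) + 5
    sds = t.counts.std(axis=1, ddof=1).to_numpy()
    assert abs(sds[0] - 15.8) < 4


def test_phenotype_pure_noise_limit(small_G):
    cfg = SimulationConfig(h2_true=0.0, m2_true=0.0, var_total=2.0, seed=7)
    draws = [simulate_phenotype(small_G, None, cfg,
                                rng=np.random.default_rng(s)).trait("y1")
             for s in range(200)]
    v = np.var(np.concatenate([d.to_numpy() for d in draws]), ddof=1)
    np.testing.assert_allclose(v, 2.0, rtol=0.05)


def test_phenotype_variance_of_u_matches_sigma2_u(small_G):
    # empirical Var(u)/sigma2_u -> 1 over replicates (tolerance 3/sqrt(reps))
    cfg = SimulationConfig(h2_true=0.5, m2_true=0.0, seed=8)
    reps = 400
    ratios = []
    for s in range(reps):
        t = simulate_phenotype(small_G, None, cfg,
                               rng=np.random.default_rng(s))
        u = t.true_values["u"]
        ratios.append(np.mean(u**2) / t.true_values["sigma2_u"])
    # E[u_i^2] = sigma2_u * G_ii; diag of the GRM averages 1
    expected = np.diag(small_G.values).mean()
    assert abs(np.mean(ratios) - expected) < 3.0 / np.sqrt(reps)


def test_phenotype_warns_for_identity_like_kernel():
    I = KernelMatrix([f"s{i}" for i in range(20)], np.eye(20))
    cfg = SimulationConfig(h2_true=0.9, m2_true=0.0, seed=9)
    with pytest.warns(UserWarning, match="identity"):
        simulate_phenotype(I, None, cfg)


def test_bivariate_perfect_correlation_duplicates_effects(small_G):
    cfg = SimulationConfig(h2_true=0.4, h2_true_2=0.4, rg_true=1.0,
                           m2_true=0.0, seed=10)
    t = simulate_bivariate_phenotypes(small_G, cfg)
    np.testing.assert_allclose(t.true_values["u1"], t.true_values["u2"],
                               atol=1e-10)


def test_bivariate_zero_correlation_is_null(small_G):
    cfg = SimulationConfig(h2_true=0.5, rg_true=0.0, m2_true=0.0, seed=11)
    cors = []
    for s in range(100):
        t = simulate_bivariate_phenotypes(small_G, cfg,
                                          rng=np.random.default_rng(s))
        cors.append(np.corrcoef(t.true_values["u1"], t.true_values["u2"])[0, 1])
    assert abs(np.mean(cors)) < 3 * np.std(cors) / np.sqrt(len(cors)) + 0.02


def test_growth_records_zero_noise_monotone_and_exact_rfi(small_G,
                                                          small_config):
    rec, _ = simulate_growth_records(small_G, small_config, noise_sd=0.0,
                                     rfi_sd=0.0)
    bw = rec.pivot(index="id", columns="week", values="bw")
    assert (bw.diff(axis=1).iloc[:, 1:] >= 0).all().all()
    phenos, _ = derive_phenotypes(rec)
    # intake is exactly linear in the regressors: residuals vanish
    assert phenos["RFI6"].abs().max() < 1e-8


def test_growth_chain_fcr_calibration():
    cfg = SimulationConfig(n_individuals=400, n_snps=400, seed=12)
    geno = simulate_genotypes(cfg)
    G = grm_vanraden(geno.dosages, geno.sample_ids)
    rec, _ = simulate_growth_records(G, cfg)
    phenos, _ = derive_phenotypes(rec)
    assert abs(phenos["FCR6"].mean() - 2.12) < 0.15
    assert abs(phenos["BW6"].mean() - 1408) < 120


def test_cohort_ids_consistent_and_deterministic(small_config):
    c1 = simulate_cohort(small_config)
    c2 = simulate_cohort(small_config)
    assert c1.genotypes.sample_ids == c1.asv_counts.sample_ids
    assert set(c1.O.ids) <= set(c1.G.ids)
    assert list(c1.phenotypes.index) == c1.genotypes.sample_ids
    np.testing.assert_array_equal(c1.genotypes.dosages, c2.genotypes.dosages)
    pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)
    np.testing.assert_array_equal(c1.trait.y.to_numpy(), c2.trait.y.to_numpy())


def test_cohort_roundtrips_through_writers(tmp_path, small_config):
    from mgblup.genotypes import read_vcf
    from mgblup.microbiome import ASVTable
    from mgblup.simulate import write_cohort

    cohort = simulate_cohort(small_config)
    paths = write_cohort(cohort, tmp_path)
    geno = read_vcf(paths["genotypes"])
    np.testing.assert_array_equal(geno.dosages, cohort.genotypes.dosages)
    asv = ASVTable.from_tsv(paths["asv_counts"])
    pd.testing.assert_frame_equal(asv.counts, cohort.asv_counts.counts)
    growth = pd.read_csv(paths["growth"])
    pd.testing.assert_frame_equal(growth, cohort.growth)
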