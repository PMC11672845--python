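"""AI-REML engine: likelihood, optimisation, ratios, bivariate model, SEs."""

import numpy as np
import pandas as pd
import pytest

from mgblup.kernels import KernelMatrix, grm_vanraden
from mgblup.simulate import (SimulationConfig, simulate_bivariate_phenotypes,
                             simulate_genotypes, simulate_phenotype)
from mgblup.varcomp import (BivariateKernelModel, KernelMixedModel, REMLError,
                            VarCompEstimate, KernelMixedResults,
                            fit_bivariate_reml, fit_reml, reml_loglik)


def _sim_fixture(n=50, n_snps=150, h2=0.5, seed=0):
    cfg = SimulationConfig(n_individuals=n, n_snps=n_snps, h2_true=h2,
                           m2_true=0.0, seed=seed)
    geno = simulate_genotypes(cfg)
    G = grm_vanraden(geno.dosages, geno.sample_ids)
    ph = simulate_phenotype(G, None, cfg)
    return G, ph.trait("y1")


def _loglik_reference(y, K_list, sigma2):
    """Independent dense evaluation: explicit inverse + slogdet, no Cholesky."""
    n = y.size
    V = sigma2[-1] * np.eye(n)
    for s, K in zip(sigma2[:-1], K_list):
        V = V + s * K
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ld_v + ld_x + y @ P @ y))


def test_loglik_matches_independent_evaluation():
    G, y = _sim_fixture(n=5, n_snps=30, seed=1)
    sigma2 = np.array([0.7, 0.4])
    ours = reml_loglik(y.to_numpy(), [G.values], sigma2)
    ref = _loglik_reference(y.to_numpy(), [G.values], sigma2)
    assert ours == pytest.approx(ref, abs=1e-10)


def test_loglik_identity_kernel_ridge():
    # with G = I the likelihood depends only on sigma2_u + sigma2_e
    rng = np.random.default_rng(2)
    y = rng.normal(0, 1, 30)
    I = np.eye(30)
    vals = [reml_loglik(y, [I], np.array([a, 1.0 - a]))
            for a in (0.1, 0.3, 0.5, 0.7)]
    assert max(vals) - min(vals) < 1e-8


def test_loglik_invariant_to_phenotype_shift():
    G, y = _sim_fixture(n=20, n_snps=60, seed=3)
    s = np.array([0.5, 0.5])
    a = reml_loglik(y.to_numpy(), [G.values], s)
    b = reml_loglik(y.to_numpy() + 100.0, [G.values], s)
    assert a == pytest.approx(b, abs=1e-8)


def test_loglik_input_validation():
    G, y = _sim_fixture(n=10, n_snps=30, seed=4)
    with pytest.raises(REMLError):
        reml_loglik(y.to_numpy(), [G.values], np.array([1.0]))
    with pytest.raises(REMLError):
        reml_loglik(y.to_numpy(), [G.values], np.array([-0.1, 1.0]))


def _grid_argmax_h2(y, K, n_grid=200):
    """Profile grid-search oracle over h2 with the scale maximised analytically.

    V = s * V0(h2), V0 = h2*K + (1-h2)*I; the REML-optimal s has the closed
    form s = y'P0 y / (n - 1).
    """
    n = y.size
    X = np.ones((n, 1))
    best, best_ll = None, -np.inf
    for h2 in np.linspace(0.001, 0.999, n_grid):
        V0 = h2 * K + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        P0 = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        yPy = y @ P0 @ y
        s = yPy / (n - 1)
        _, ld_v = np.linalg.slogdet(V0)
        _, ld_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (n * np.log(s) + ld_v - np.log(s) + ld_x + yPy / s)
        if ll > best_ll:
            best, best_ll = h2, ll
    return best


@pytest.mark.parametrize("seed", range(5))
def test_fit_matches_grid_search_oracle(seed):
    G, y = _sim_fixture(n=50, n_snps=150, h2=0.4 + 0.05 * seed, seed=seed)
    res = fit_reml(y, [G])
    assert res.converged
    h2_hat = res.ratios["h2"]
    K = G.values + 1e-8 * np.eye(G.n)  # same jitter as the fit
    h2_grid = _grid_argmax_h2(y.to_numpy(), K)
    assert abs(h2_hat - h2_grid) <= (0.999 - 0.001) / 199 + 1e-6


def test_null_heritability_piles_at_zero():
    ests = []
    for seed in range(15):
        G, y = _sim_fixture(n=150, n_snps=300, h2=0.0, seed=seed)
        res = fit_reml(y, [G])
        ests.append(res.ratios["h2"])
    assert np.mean(ests) < 0.05
    assert min(ests) < 1e-4  # boundary pile-up


def test_moderate_h2_recovery_small_scale():
    ests = []
    for seed in range(10):
        G, y = _sim_fixture(n=200, n_snps=500, h2=0.5, seed=100 + seed)
        ests.append(fit_reml(y, [G]).ratios["h2"])
    ests = np.array(ests)
    sem = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - 0.5) < 2 * sem + 0.02


def test_likelihood_ascends_along_trace():
    G, y = _sim_fixture(n=80, n_snps=200, h2=0.4, seed=5)
    res = fit_reml(y, [G])
    trace = np.array(res.llf_trace)
    assert (np.diff(trace) >= -1e-9).all()


def test_scale_equivariance():
    G, y = _sim_fixture(n=80, n_snps=200, h2=0.5, seed=6)
    r1 = fit_reml(y, [G])
    r2 = fit_reml(y * 10.0, [G])
    np.testing.assert_allclose(r2.estimate.sigma2, 100.0 * r1.estimate.sigma2,
                               rtol=1e-4)
    assert r2.ratios["h2"] == pytest.approx(r1.ratios["h2"], abs=1e-5)


def test_permutation_invariance():
    G, y = _sim_fixture(n=60, n_snps=150, h2=0.5, seed=7)
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(G.ids))
    r1 = fit_reml(y, [G])
    r2 = fit_reml(y.loc[perm], [G.subset(perm)])
    np.testing.assert_allclose(r1.estimate.sigma2, r2.estimate.sigma2,
                               rtol=1e-5)


def test_misaligned_ids_error():
    G, y = _sim_fixture(n=20, n_snps=60, seed=8)
    y2 = y.copy()
    y2.index = [f"zz{i}" for i in range(20)]
    with pytest.raises(REMLError):
        KernelMixedModel(y2, [G])


def test_duplicate_kernel_kinds_rejected():
    G, y = _sim_fixture(n=20, n_snps=60, seed=9)
    with pytest.raises(REMLError, match="duplicated"):
        KernelMixedModel(y, [G, G])


def test_derive_ratio_arithmetic():
    # sigma2 = (u=2, m=1, e=1): h2_bar = 0.5, m2_bar = 0.25
    est = VarCompEstimate(np.array([2.0, 1.0, 1.0]),
                          ["genomic", "microbial", "residual"],
                          np.eye(3) * 1e-4)
    res = KernelMixedResults(model=None, estimate=est, converged=True,
                             n_iter=5, llf_trace=[0.0])
    assert res.ratios["h2_bar"] == pytest.approx(0.5)
    assert res.ratios["m2_bar"] == pytest.approx(0.25)
    # sigma2_u = sigma2_e -> single-kernel h2 = 0.5
    est1 = VarCompEstimate(np.array([3.0, 3.0]), ["genomic", "residual"],
                           np.eye(2) * 1e-4)
    res1 = KernelMixedResults(model=None, estimate=est1, converged=True,
                              n_iter=5, llf_trace=[0.0])
    assert res1.ratios["h2"] == pytest.approx(0.5)
    # sigma2_m = 0 in the joint fit: h2_bar equals the GBLUP-style ratio
    est2 = VarCompEstimate(np.array([2.0, 0.0, 1.0]),
                           ["genomic", "microbial", "residual"],
                           np.eye(3) * 1e-4)
    res2 = KernelMixedResults(model=None, estimate=est2, converged=True,
                              n_iter=5, llf_trace=[0.0])
    assert res2.ratios["h2_bar"] == pytest.approx(2.0 / 3.0)


def test_nonconverged_fit_reports_no_ratios():
    est = VarCompEstimate(np.array([1.0, 1.0]), ["genomic", "residual"],
                          np.eye(2))
    res = KernelMixedResults(model=None, estimate=est, converged=False,
                             n_iter=200, llf_trace=[0.0], reason="max_iter")
    assert res.ratios is None
    with pytest.raises(REMLError):
        res.monte_carlo_se()


def test_monte_carlo_se_degenerate_and_stability():
    est = VarCompEstimate(np.array([1.0, 1.0]), ["genomic", "residual"],
                          np.zeros((2, 2)))
    res = KernelMixedResults(model=None, estimate=est, converged=True,
                             n_iter=3, llf_trace=[0.0])
    assert res.monte_carlo_se(n_draws=100, seed=1)["h2"] == 0.0

    G, y = _sim_fixture(n=100, n_snps=250, h2=0.5, seed=10)
    fit = fit_reml(y, [G])
    a = fit.monte_carlo_se(n_draws=20000, seed=1)["h2"]
    b = fit.monte_carlo_se(n_draws=40000, seed=2)["h2"]
    assert abs(a - b) / a < 0.05


def test_monte_carlo_se_matches_delta_method():
    # h2 = su/(su+se): delta-method variance g' C g with
    # g = (se, -su) / (su+se)^2; agreement requires the asymptotic
    # covariance to be small enough for the ratio to be near-linear
    G, y = _sim_fixture(n=400, n_snps=600, h2=0.5, seed=11)
    fit = fit_reml(y, [G])
    su, se_ = fit.estimate.sigma2
    C = fit.estimate.cov
    g = np.array([se_, -su]) / (su + se_) ** 2
    delta = float(np.sqrt(g @ C @ g))
    mc = fit.monte_carlo_se(n_draws=100_000, seed=3)["h2"]
    assert abs(mc - delta) / delta < 0.05


def test_summary_is_informative():
    G, y = _sim_fixture(n=60, n_snps=150, h2=0.5, seed=12)
    res = fit_reml(y, [G])
    text = res.summary()
    assert "AI-REML" in text and "h2" in text and "converged = True" in text


def test_block_evaluator_matches_dense_likelihood():
    # the eigen-rotated O(n) evaluator must reproduce the dense REML
    # log-likelihood exactly (orthogonal rotation leaves it unchanged)
    from mgblup.varcomp import _BlockEvaluator, _pmat

    G, y = _sim_fixture(n=40, n_snps=100, h2=0.5, seed=20)
    n = G.n
    K = G.values + 1e-8 * np.eye(n)
    theta = np.array([0.6, 0.5])
    # univariate block form
    w, E = np.linalg.eigh(K)
    ev = _BlockEvaluator((E.T @ y.to_numpy())[:, None],
                         (E.T @ np.ones(n))[:, None, None],
                         [w[:, None, None], np.ones((n, 1, 1))])
    ll_block = ev.loglik(theta)[0]
    V = theta[0] * K + theta[1] * np.eye(n)
    ll_dense = _pmat(y.to_numpy(), np.ones((n, 1)), V)[2]
    assert ll_block == pytest.approx(ll_dense, abs=1e-8)

    # bivariate block form vs dense Kronecker construction
    rng = np.random.default_rng(21)
    y2 = rng.normal(0, 1, n)
    theta6 = np.array([0.5, 0.2, 0.6, 0.5, -0.1, 0.7])
    basis = [np.array([[1.0, 0], [0, 0]]), np.array([[0, 1.0], [1.0, 0]]),
             np.array([[0, 0], [0, 1.0]])]
    mats = [np.kron(B, K) for B in basis] + [np.kron(B, np.eye(n))
                                             for B in basis]
    Vd = sum(t * M for t, M in zip(theta6, mats))
    yy = np.concatenate([y.to_numpy(), y2])
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    ll_dense2 = _pmat(yy, X, Vd)[2]
    yt = np.column_stack([E.T @ y.to_numpy(), E.T @ y2])
    Xt = np.einsum("n,jp->njp", E.T @ np.ones(n), np.eye(2))
    Kb = [B[None] * w[:, None, None] for B in basis]
    Kb += [np.broadcast_to(B, (n, 2, 2)).copy() for B in basis]
    ev2 = _BlockEvaluator(yt, Xt, Kb)
    assert ev2.loglik(theta6)[0] == pytest.approx(ll_dense2, abs=1e-8)


# ------------------------------------------------------------------ bivariate

def test_bivariate_duplicated_trait_rg_at_boundary():
    # an exactly duplicated trait drives the genetic correlation to the
    # rg = 1 boundary, where V degenerates; the estimate sits at the
    # boundary whether or not the fit is declared converged
    G, y = _sim_fixture(n=80, n_snps=200, h2=0.6, seed=13)
    res = fit_bivariate_reml(y, y.copy(), G)
    t = res.params
    rg_raw = t["su_12"] / np.sqrt(t["su2_1"] * t["su2_2"])
    assert rg_raw == pytest.approx(1.0, abs=0.02)


def test_bivariate_near_duplicate_trait_converges_high_rg():
    G, y = _sim_fixture(n=80, n_snps=200, h2=0.6, seed=13)
    y2 = y + np.random.default_rng(0).normal(0, 0.3 * y.std(), len(y))
    res = fit_bivariate_reml(y, pd.Series(y2, index=y.index), G)
    assert res.converged
    assert res.rg > 0.9


def test_bivariate_null_correlation():
    rgs = []
    for seed in range(8):
        cfg = SimulationConfig(n_individuals=150, n_snps=400, h2_true=0.6,
                               rg_true=0.0, m2_true=0.0, seed=40 + seed)
        geno = simulate_genotypes(cfg)
        G = grm_vanraden(geno.dosages, geno.sample_ids)
        ph = simulate_bivariate_phenotypes(G, cfg)
        res = fit_bivariate_reml(ph.trait("y1"), ph.trait("y2"), G)
        if res.converged and res.rg is not None:
            rgs.append(res.rg)
    rgs = np.array(rgs)
    sem = rgs.std(ddof=1) / np.sqrt(len(rgs))
    assert abs(rgs.mean()) < 2 * sem + 0.05


def test_bivariate_blocks_psd_and_rg_bounded():
    G, y = _sim_fixture(n=100, n_snps=250, h2=0.5, seed=14)
    cfg = SimulationConfig(n_individuals=100, n_snps=250, h2_true=0.5,
                           rg_true=0.8, m2_true=0.0, seed=15)
    ph = simulate_bivariate_phenotypes(G, cfg)
    res = fit_bivariate_reml(ph.trait("y1"), ph.trait("y2"), G)
    t = res.params
    Ku = np.array([[t["su2_1"], t["su_12"]], [t["su_12"], t["su2_2"]]])
    Ke = np.array([[t["se2_1"], t["se_12"]], [t["se_12"], t["se2_2"]]])
    assert np.linalg.eigvalsh(Ku).min() >= -1e-8
    assert np.linalg.eigvalsh(Ke).min() >= -1e-8
    assert res.rg is not None and -1.0 <= res.rg <= 1.0
    assert res.monte_carlo_se(n_draws=2000, seed=0) >= 0.0


def test_bivariate_too_few_complete_cases():
    G = KernelMatrix([f"s{i}" for i in range(5)], np.eye(5))
    y = pd.Series(np.arange(5.0), index=G.ids)
    with pytest.raises(REMLError, match="complete cases"):
        BivariateKernelModel(y, y, G)
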