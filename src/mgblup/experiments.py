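"""Seeded parameter-recovery experiments on synthetic cohorts.

Each experiment simulates replicate cohorts under the default desk-scale
study conditions (400 individuals, 2,000 SNPs, 300 ASVs), fits the
corresponding kernel mixed model by AI-REML, and returns the per-replicate
estimates.  Replicate ``r`` uses master seed ``base_seed + r``, so a run is
fully reproducible from ``base_seed``.
"""

from __future__ import annotations

import numpy as np

from .kernels import grm_vanraden, microbial_similarity
from .microbiome import filter_samples, filter_sparse_asvs, rarefy, \
    log_center_scale
from .simulate import (SimulationConfig, simulate_genotypes,
                       simulate_asv_counts, simulate_phenotype,
                       simulate_bivariate_phenotypes)
from .varcomp import fit_reml, fit_bivariate_reml

__all__ = [
    "h2_recovery",
    "rg_recovery",
    "joint_m2_recovery",
    "pearson_recovery",
    "summarize",
]


def _replicate_config(base_seed: int, rep: int, **kwargs) -> SimulationConfig:
    return SimulationConfig(seed=int(base_seed) + rep, **kwargs)


def _build_g(config: SimulationConfig):
    geno = simulate_genotypes(config)
    return grm_vanraden(geno.dosages, geno.sample_ids)


def h2_recovery(
    h2_true: float,
    n_reps: int = 20,
    base_seed: int = 1,
    n_individuals: int = 400,
    n_snps: int = 2000,
) -> np.ndarray:
    """GBLUP heritability estimates over seeded replicate cohorts."""
    out = []
    for rep in range(n_reps):
        cfg = _replicate_config(
            base_seed, rep, n_individuals=n_individuals, n_snps=n_snps,
            h2_true=h2_true, m2_true=0.0,
        )
        G = _build_g(cfg)
        ph = simulate_phenotype(G, None, cfg)
        res = fit_reml(ph.trait("y1"), [G])
        out.append(res.ratios["h2"] if res.converged else np.nan)
    return np.asarray(out)


def rg_recovery(
    rg_true: float,
    h2_1: float,
    h2_2: float,
    n_reps: int = 20,
    base_seed: int = 1,
    n_individuals: int = 400,
    n_snps: int = 2000,
) -> np.ndarray:
    """Bivariate genetic-correlation estimates over seeded replicates."""
    out = []
    for rep in range(n_reps):
        cfg = _replicate_config(
            base_seed, rep, n_individuals=n_individuals, n_snps=n_snps,
            h2_true=h2_1, h2_true_2=h2_2, rg_true=rg_true, m2_true=0.0,
        )
        G = _build_g(cfg)
        ph = simulate_bivariate_phenotypes(G, cfg)
        res = fit_bivariate_reml(ph.trait("y1"), ph.trait("y2"), G)
        out.append(res.rg if res.converged and res.rg is not None else np.nan)
    return np.asarray(out)


def joint_m2_recovery(
    h2_true: float,
    m2_true: float = 0.0,
    n_reps: int = 20,
    base_seed: int = 1,
    n_individuals: int = 400,
    n_snps: int = 2000,
    n_asvs: int = 300,
) -> np.ndarray:
    """MGBLUP direct microbiability (m2-bar) estimates over replicates.

    The microbial kernel is built through the full QC chain (sample filter,
    prevalence filter, rarefaction, log/centre/scale), so the experiment
    exercises exactly the analysis path real data would take.
    """
    out = []
    for rep in range(n_reps):
        cfg = _replicate_config(
            base_seed, rep, n_individuals=n_individuals, n_snps=n_snps,
            n_asvs=n_asvs, h2_true=h2_true, m2_true=m2_true,
        )
        G = _build_g(cfg)
        asv = simulate_asv_counts(cfg)
        filt, _ = filter_samples(asv)
        filt, _ = filter_sparse_asvs(filt)
        rare = rarefy(filt, seed=cfg.seed)
        transformed = log_center_scale(rare)
        O = microbial_similarity(transformed.sample_matrix,
                                 transformed.sample_ids)
        Gsub = G.subset(O.ids)
        ph = simulate_phenotype(Gsub, O, cfg)
        res = fit_reml(ph.trait("y1"), [Gsub, O])
        out.append(res.ratios["m2_bar"] if res.converged else np.nan)
    return np.asarray(out)


def pearson_recovery(
    rho: float,
    n: int = 400,
    n_reps: int = 20,
    base_seed: int = 1,
) -> np.ndarray:
    """Pearson correlation estimates from bivariate normal samples.

    Routed through :func:`mgblup.phenotypes.phenotypic_correlations` so the
    pairwise-complete machinery is what gets exercised.
    """
    import pandas as pd

    from .phenotypes import phenotypic_correlations

    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(int(base_seed) + rep)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        df = pd.DataFrame(xy, columns=["x", "y"])
        r, _ = phenotypic_correlations(df)
        out.append(float(r.loc["x", "y"]))
    return np.asarray(out)


def summarize(estimates: np.ndarray) -> dict:
    """Mean, SD and Monte-Carlo SE of the mean over converged replicates."""
    est = np.asarray(estimates, float)
    ok = est[~np.isnan(est)]
    return {
        "mean": float(ok.mean()),
        "sd": float(ok.std(ddof=1)),
        "se_mean": float(ok.std(ddof=1) / np.sqrt(ok.size)),
        "n_converged": int(ok.size),
        "n_total": int(est.size),
    }
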