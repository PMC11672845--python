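"""Synthetic cohort generator: genotypes, ASV counts, growth and phenotypes.

The generator emulates a single-hatch broiler cohort of ~400 individually
fed males: a few thousand biallelic SNPs with autoregressive linkage
disequilibrium, a sparse amplicon (ASV) count table, weekly body-weight and
feed-intake records from four to ten weeks, and phenotypes drawn from the
kernel mixed model

    y = mu + u + m + e,  u ~ N(0, G sigma2_u),  m ~ N(0, O sigma2_m),
    e ~ N(0, I sigma2_e)

with sigma2_u = h2_true * var_total, sigma2_m = m2_true * var_total, and the
remainder residual.  Every artifact is reproducible from the config seed.

Genotypes come from a first-order autoregressive Gaussian copula: each of
the two haplotypes per individual carries a latent AR(1) process across
markers (lag-one correlation ``ld_rho``) thresholded at the allele-frequency
quantile, so markers are in Hardy-Weinberg proportions marginally while
adjacent markers stay correlated.  ASV counts are multinomial draws from a
log-normal community profile with per-sample log-normal perturbation; the
profile's log-SD is calibrated at generation time so the realised zero
fraction tracks ``sparsity_target``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kernels import KernelMatrix, KernelError, grm_vanraden, microbial_similarity
from .microbiome import ASVTable, filter_samples, filter_sparse_asvs, rarefy, \
    log_center_scale
from .phenotypes import derive_phenotypes

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "SimulatedPhenotype",
    "ConfigError",
    "simulate_genotypes",
    "simulate_asv_counts",
    "simulate_phenotype",
    "simulate_bivariate_phenotypes",
    "simulate_growth_records",
    "simulate_cohort",
    "write_cohort",
]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the desk-scale cohort used throughout: 400
    individuals, 2,000 SNPs (MAF uniform on [0.05, 0.5], adjacent-marker
    copula correlation 0.95 at 2.5 Kb spacing), 300 ASVs at a mean depth of
    20,000 reads with ~50% zero cells, and a unit-variance trait.
    """

    n_individuals: int = 400
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.95
    pos_spacing_bp: int = 2500
    missing_rate: float = 0.0
    n_asvs: int = 300
    depth_mean: float = 20000.0
    depth_sd: float = 5000.0
    depth_min: int = 100
    sparsity_target: float = 0.5
    sample_lognorm_sd: float = 1.0
    mu: float = 0.0
    var_total: float = 1.0
    h2_true: float = 0.3
    h2_true_2: float | None = None  # second trait (bivariate); defaults to h2_true
    m2_true: float = 0.1
    rg_true: float = 0.5
    re_true: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for name in ("h2_true", "m2_true"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1)")
        h2b = self.h2_true if self.h2_true_2 is None else self.h2_true_2
        if not (0 <= h2b < 1):
            raise ConfigError("h2_true_2 must be in [0, 1)")
        if self.h2_true + self.m2_true >= 1:
            raise ConfigError("h2_true + m2_true must be < 1")
        if not (-1 <= self.rg_true <= 1):
            raise ConfigError("rg_true must be in [-1, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.var_total <= 0:
            raise ConfigError("var_total must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for artifact ``stream`` under the master seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(
            stream + 1)[stream])


def _sample_ids(n: int) -> list[str]:
    return [f"B{i+1:04d}" for i in range(n)]


# ------------------------------------------------------------------ genotypes

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosage matrix under HWE with AR(1)-copula linkage disequilibrium."""
    n, m = config.n_individuals, config.n_snps
    if n < 2 or m < 1:
        raise ConfigError("need n_individuals >= 2 and n_snps >= 1")
    rng = config.rng(0)
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    thresh = stats.norm.ppf(p)

    dosage = np.zeros((n, m))
    rho = config.ld_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    for _hap in range(2):
        eps = rng.standard_normal((n, m))
        x = np.empty((n, m))
        x[:, 0] = eps[:, 0]
        for j in range(1, m):
            x[:, j] = rho * x[:, j - 1] + innov_sd * eps[:, j]
        dosage += (x < thresh).astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    markers = pd.DataFrame(
        {
            "id": [f"SNP{j+1:05d}" for j in range(m)],
            "chrom": "1",
            "pos": 1 + np.arange(m) * config.pos_spacing_bp,
        }
    )
    return GenotypeMatrix(_sample_ids(n), markers, dosage)


# ----------------------------------------------------------------- ASV counts

def _quantile_profile(n_asvs: int, log_sd: float) -> np.ndarray:
    """Log-abundance profile at the lognormal quantiles.

    Fixing the profile to the quantiles (rather than drawing it) keeps the
    realised sparsity stable across seeds: only sample-level perturbation
    and depth vary.
    """
    return log_sd * stats.norm.ppf((np.arange(n_asvs) + 0.5) / n_asvs)


def _zero_fraction(log_sd: float, config: SimulationConfig,
                   rng: np.random.Generator, n_probe: int = 40) -> float:
    """Realised zero fraction of a probe table at a candidate profile log-SD."""
    base = _quantile_profile(config.n_asvs, log_sd)
    zeros = 0
    for _ in range(n_probe):
        logit = base + rng.normal(0.0, config.sample_lognorm_sd, config.n_asvs)
        prob = np.exp(logit - logit.max())
        prob /= prob.sum()
        depth = max(config.depth_min, int(round(rng.normal(
            config.depth_mean, config.depth_sd))))
        counts = rng.multinomial(depth, prob)
        zeros += (counts == 0).mean()
    return zeros / n_probe


def _calibrate_log_sd(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Bisect the community-profile log-SD to hit the target zero fraction."""
    lo, hi = 0.0, 8.0
    for _ in range(25):
        mid = (lo + hi) / 2.0
        if _zero_fraction(mid, config, rng) < config.sparsity_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_asv_counts(config: SimulationConfig) -> ASVTable:
    """Multinomial ASV counts from a log-normal community profile.

    Library sizes are Normal(depth_mean, depth_sd) truncated at
    ``depth_min`` reads; column sums equal the drawn library sizes exactly.
    """
    if config.n_asvs < 2:
        raise ConfigError("need n_asvs >= 2")
    rng = config.rng(1)
    log_sd = _calibrate_log_sd(config, np.random.default_rng(rng.integers(2**31)))
    base = rng.permutation(_quantile_profile(config.n_asvs, log_sd))

    n = config.n_individuals
    counts = np.empty((config.n_asvs, n), dtype=np.int64)
    for s in range(n):
        logit = base + rng.normal(0.0, config.sample_lognorm_sd, config.n_asvs)
        prob = np.exp(logit - logit.max())
        prob /= prob.sum()
        depth = max(config.depth_min,
                    int(round(rng.normal(config.depth_mean, config.depth_sd))))
        counts[:, s] = rng.multinomial(depth, prob)

    return ASVTable(
        pd.DataFrame(
            counts,
            index=[f"ASV{i+1:04d}" for i in range(config.n_asvs)],
            columns=_sample_ids(n),
        )
    )


# ----------------------------------------------------------------- phenotypes

def _kernel_root(K: KernelMatrix, jitter: float = 1e-8) -> np.ndarray:
    """Square root of a PSD kernel via eigendecomposition.

    Negative eigenvalues within the numerical floor are clipped at zero
    (kernels are rank-deficient when markers < individuals, so Cholesky is
    not applicable); anything more negative is a hard error.
    """
    A = K.values + jitter * np.eye(K.n)
    w, V = np.linalg.eigh(A)
    if w.min() < -1e-8:
        raise KernelError(
            f"kernel '{K.kind}' not PSD after jitter (min eig {w.min():.2e})"
        )
    return V * np.sqrt(np.maximum(w, 0.0))


def _warn_if_identity_like(K: KernelMatrix) -> None:
    off = K.values - np.diag(np.diag(K.values))
    d = np.diag(K.values)
    if np.abs(off).max() < 1e-6 * max(d.mean(), 1e-12) and d.std() < 1e-6 * d.mean():
        warnings.warn(
            f"kernel '{K.kind}' is numerically proportional to the identity; "
            "its variance component is confounded with the residual",
            stacklevel=2,
        )


@dataclass
class SimulatedPhenotype:
    """Phenotype draw(s) with the true effect vectors and components."""

    y: pd.DataFrame  # one column per trait, indexed by individual id
    true_values: dict = field(default_factory=dict)

    def trait(self, name: str = "y1") -> pd.Series:
        return self.y[name]


def simulate_phenotype(
    G: KernelMatrix | None,
    O: KernelMatrix | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedPhenotype:
    """Single-trait draw y = mu + u + m + e (one record per individual)."""
    if rng is None:
        rng = config.rng(2)
    ref = G if G is not None else O
    if ref is None:
        raise ConfigError("at least one kernel is required")
    if G is not None and O is not None and G.ids != O.ids:
        raise KernelError("G and O sample ids differ")
    n = ref.n
    s_u = config.h2_true * config.var_total
    s_m = config.m2_true * config.var_total
    s_e = (1.0 - config.h2_true - config.m2_true) * config.var_total

    u = np.zeros(n)
    m = np.zeros(n)
    if s_u > 0:
        if G is None:
            raise ConfigError("h2_true > 0 requires a genomic kernel")
        _warn_if_identity_like(G)
        u = _kernel_root(G) @ rng.standard_normal(n) * np.sqrt(s_u)
    if s_m > 0:
        if O is None:
            raise ConfigError("m2_true > 0 requires a microbial kernel")
        _warn_if_identity_like(O)
        m = _kernel_root(O) @ rng.standard_normal(n) * np.sqrt(s_m)
    e = rng.standard_normal(n) * np.sqrt(s_e)
    y = config.mu + u + m + e
    return SimulatedPhenotype(
        y=pd.DataFrame({"y1": y}, index=pd.Index(ref.ids, name="id")),
        true_values={
            "u": u, "m": m, "e": e,
            "sigma2_u": s_u, "sigma2_m": s_m, "sigma2_e": s_e,
            "h2_true": config.h2_true, "m2_true": config.m2_true,
        },
    )


def simulate_bivariate_phenotypes(
    G: KernelMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedPhenotype:
    """Two traits with genetic covariance K (x) G, residual correlation re_true.

    Trait heritabilities are ``h2_true`` and ``h2_true_2`` (both on
    var_total); the genetic covariance is rg_true * sigma_u1 * sigma_u2.
    """
    if rng is None:
        rng = config.rng(3)
    n = G.n
    h1 = config.h2_true
    h2 = config.h2_true if config.h2_true_2 is None else config.h2_true_2
    vt = config.var_total
    su1, su2 = h1 * vt, h2 * vt
    K = np.array(
        [
            [su1, config.rg_true * np.sqrt(su1 * su2)],
            [config.rg_true * np.sqrt(su1 * su2), su2],
        ]
    )
    if np.linalg.eigvalsh(K).min() < -1e-12:
        raise ConfigError("genetic (co)variance block is not PSD")
    se1, se2 = (1 - h1) * vt, (1 - h2) * vt
    Ke = np.array(
        [
            [se1, config.re_true * np.sqrt(se1 * se2)],
            [config.re_true * np.sqrt(se1 * se2), se2],
        ]
    )

    def root2(B):
        w, V = np.linalg.eigh(B)
        return V * np.sqrt(np.maximum(w, 0.0))

    Lg = _kernel_root(G)
    U = Lg @ rng.standard_normal((n, 2)) @ root2(K).T  # cov (vec U) = K (x) G
    E = rng.standard_normal((n, 2)) @ root2(Ke).T
    Y = config.mu + U + E
    return SimulatedPhenotype(
        y=pd.DataFrame(Y, index=pd.Index(G.ids, name="id"),
                       columns=["y1", "y2"]),
        true_values={
            "u1": U[:, 0], "u2": U[:, 1],
            "K_genetic": K, "K_residual": Ke, "rg_true": config.rg_true,
        },
    )


# ------------------------------------------------------------- growth records

#: logistic growth-curve defaults fitted to a 4-10 week broiler trajectory
GROWTH = {
    "asymptote_g": 3600.0,
    "rate_per_day": 0.064,
    "inflection_day": 49.3,
    "cv_asymptote": 0.12,
    "bw_h2": 0.15,
    "bw_noise_sd": 15.0,
    "fi_intercept": -7.6,      # g/day
    "fi_b_adg": 0.5,
    "fi_c_mbw": 0.45,          # g/day per g^0.75
    "rfi_sd": 6.0,             # g/day, total SD of the intake deviation
}


def simulate_growth_records(
    G: KernelMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    rfi_h2: float | None = None,
    noise_sd: float | None = None,
    rfi_sd: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Weekly BW and FI records (long format: id, week, bw, fi).

    Body weights follow a logistic curve with an individual asymptote whose
    log-scale variation has a genetic fraction drawn from G; daily feed
    intake per week is a + b*ADG + c*MBW^0.75 + delta_i, where the
    individual deviation delta has genetic fraction ``rfi_h2`` (defaults to
    config.h2_true), so the heritability of the derived residual feed
    intake is controlled.
    """
    if rng is None:
        rng = config.rng(4)
    if rfi_h2 is None:
        rfi_h2 = config.h2_true
    if noise_sd is None:
        noise_sd = GROWTH["bw_noise_sd"]
    n = G.n
    Lg = _kernel_root(G)
    g_bw = Lg @ rng.standard_normal(n)
    g_rfi = Lg @ rng.standard_normal(n)

    cv = GROWTH["cv_asymptote"]
    h2bw = GROWTH["bw_h2"]
    scale = 1.0 + cv * (
        np.sqrt(h2bw) * g_bw + np.sqrt(1 - h2bw) * rng.standard_normal(n)
    )
    A = GROWTH["asymptote_g"] * np.clip(scale, 0.3, None)
    k, t0 = GROWTH["rate_per_day"], GROWTH["inflection_day"]

    weeks = np.arange(4, 11)
    days = weeks * 7.0
    bw_curve = A[:, None] / (1.0 + np.exp(-k * (days[None, :] - t0)))
    bw = bw_curve + (rng.standard_normal(bw_curve.shape) * noise_sd
                     if noise_sd > 0 else 0.0)

    sd = GROWTH["rfi_sd"] if rfi_sd is None else rfi_sd
    delta = sd * (np.sqrt(rfi_h2) * g_rfi
                  + np.sqrt(1 - rfi_h2) * rng.standard_normal(n))

    rows = []
    ids = G.ids
    for i in range(n):
        for w_idx, w in enumerate(weeks):
            if w_idx == 0:
                fi = np.nan
            else:
                adg = (bw_curve[i, w_idx] - bw_curve[i, w_idx - 1]) / 7.0
                mbw = 0.5 * (bw_curve[i, w_idx] + bw_curve[i, w_idx - 1])
                daily = (GROWTH["fi_intercept"] + GROWTH["fi_b_adg"] * adg
                         + GROWTH["fi_c_mbw"] * mbw**0.75 + delta[i])
                fi = 7.0 * daily
            rows.append((ids[i], int(w), float(bw[i, w_idx]), float(fi)))
    records = pd.DataFrame(rows, columns=["id", "week", "bw", "fi"])
    true_values = {"delta": delta, "rfi_h2": rfi_h2, "g_bw": g_bw,
                   "g_rfi": g_rfi}
    return records, true_values


# ------------------------------------------------------------------- cohort

@dataclass
class SimulatedCohort:
    """All artifacts of one synthetic cohort, with the ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    asv_counts: ASVTable
    growth: pd.DataFrame
    phenotypes: pd.DataFrame  # derived trait table
    G: KernelMatrix
    O: KernelMatrix
    trait: SimulatedPhenotype  # model-drawn single trait
    true_values: dict


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full pipeline-ready cohort under one seed.

    Generates genotypes and ASV counts, builds the G and O kernels (the ASV
    table passes the standard QC chain first), simulates growth records and
    a model-drawn trait, and derives the phenotype table from the records.
    """
    geno = simulate_genotypes(config)
    asv = simulate_asv_counts(config)
    G = grm_vanraden(geno.dosages, geno.sample_ids)

    filtered, _ = filter_samples(asv)
    filtered, _ = filter_sparse_asvs(filtered)
    rare = rarefy(filtered, seed=int(config.rng(5).integers(2**31)))
    transformed = log_center_scale(rare)
    O = microbial_similarity(transformed.sample_matrix, transformed.sample_ids)

    growth, growth_truth = simulate_growth_records(G, config)
    phenos, _ = derive_phenotypes(growth)
    Gsub = G.subset(O.ids) if O.ids != G.ids else G
    trait = simulate_phenotype(Gsub, O, config)

    return SimulatedCohort(
        config=config,
        genotypes=geno,
        asv_counts=asv,
        growth=growth,
        phenotypes=phenos,
        G=G,
        O=O,
        trait=trait,
        true_values={"growth": growth_truth, **trait.true_values},
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Persist a cohort: VCF, ASV TSV, growth CSV, phenotype CSV, truth JSON."""
    from pathlib import Path

    from .genotypes import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "asv_counts": out / "asv_counts.tsv",
        "growth": out / "growth_records.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["genotypes"])
    cohort.asv_counts.to_tsv(paths["asv_counts"])
    cohort.growth.to_csv(paths["growth"], index=False)
    cohort.phenotypes.to_csv(paths["phenotypes"])
    truth = {
        "config": asdict(cohort.config),
        "sigma2_u": cohort.true_values.get("sigma2_u"),
        "sigma2_m": cohort.true_values.get("sigma2_m"),
        "sigma2_e": cohort.true_values.get("sigma2_e"),
        "rfi_h2": cohort.true_values["growth"]["rfi_h2"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
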