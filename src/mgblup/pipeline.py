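"""End-to-end orchestration: simulate/load -> QC -> derive -> kernels -> fit.

A run is described by a :class:`RunConfig` (typically loaded from YAML) and
produces a diffable plain-text report bundle: descriptive statistics per
trait (N, Mean, SD, Min, Max), the phenotypic correlation matrix, QC
reports, a variance-ratio table with one row per trait and the four
estimate columns (GBLUP h2, MGBLUP h2-bar, MBLUP m2, MGBLUP m2-bar; "—"
marks non-converged fits), and a genetic-correlation matrix with estimates
in the lower triangle and Monte-Carlo SEs in the upper.  Every artifact can
be re-derived from the persisted intermediates, and the manifest records
the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (filter_snps, impute_missing, site_statistics, ld_decay,
                        mds_ibs, read_vcf, read_dosage_tsv, write_dosage_tsv)
from .kernels import KernelMatrix, grm_vanraden, microbial_similarity
from .microbiome import (ASVTable, filter_samples, filter_sparse_asvs, rarefy,
                         log_center_scale, alpha_diversity)
from .phenotypes import (derive_phenotypes, phenotypic_correlations,
                         descriptive_statistics, TRAITS)
from .simulate import SimulationConfig, simulate_cohort, write_cohort, ConfigError
from .varcomp import KernelMixedModel, BivariateKernelModel, derive_ratios

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``simulation`` holds generator parameters, or the input paths
    point at existing genotype / ASV / growth-record files.
    """

    outdir: str = "mgblup_run"
    seed: int = 0
    simulation: dict | None = None
    genotypes_vcf: str | None = None
    genotypes_tsv: str | None = None
    asv_tsv: str | None = None
    growth_csv: str | None = None
    call_rate_min: float = 0.9
    maf_min: float = 0.05
    hwe_p_min: float = 1e-8
    prevalence_min: float = 0.10
    outlier_sd: float = 3.5
    models: list[str] = field(default_factory=lambda: ["gblup", "mblup", "mgblup"])
    traits: list[str] | None = None  # default: all derivable traits
    bivariate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {"gblup", "mblup", "mgblup", "bivariate"}
        bad = set(self.models) - known
        if bad:
            raise ConfigError(f"unknown models: {sorted(bad)}")
        if not self.models:
            raise ConfigError("at least one model must be requested")
        for thr in (self.call_rate_min, self.maf_min, self.hwe_p_min,
                    self.prevalence_min, self.outlier_sd):
            if thr <= 0:
                raise ConfigError("thresholds must be positive")
        if self.simulation is None and self.growth_csv is None:
            raise ConfigError("either a simulation block or input paths required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        pairs = [tuple(p) for p in data.pop("bivariate_pairs", [])]
        return cls(**data, bivariate_pairs=pairs)

    def hash(self) -> str:
        blob = json.dumps(
            {k: (list(map(list, v)) if k == "bivariate_pairs" else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    ratio_table: pd.DataFrame
    rg_matrix: pd.DataFrame | None
    n_nonconverged: int
    manifest: dict


def _dash(x) -> str:
    return "—" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.3f}"


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "artifacts": {}}

    # ---------------------------------------------------------------- inputs
    needs_micro = bool({"mblup", "mgblup"} & set(config.models))
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
        cohort = simulate_cohort(sim_cfg)
        manifest["artifacts"].update(write_cohort(cohort, out / "simulated"))
        geno = cohort.genotypes
        asv = cohort.asv_counts if needs_micro else None
        growth = cohort.growth
    else:
        if config.genotypes_vcf:
            geno = read_vcf(config.genotypes_vcf)
        elif config.genotypes_tsv:
            geno = read_dosage_tsv(config.genotypes_tsv)
        else:
            raise ConfigError("no genotype input configured")
        asv = ASVTable.from_tsv(config.asv_tsv) if needs_micro else None
        growth = pd.read_csv(config.growth_csv)

    # ---------------------------------------------------------------- geno QC
    geno_f, qc_report = filter_snps(
        geno, config.call_rate_min, config.maf_min, config.hwe_p_min)
    geno_f = impute_missing(geno_f)
    qc_report.table.to_csv(out / "snp_qc_report.tsv", sep="\t", index=False)
    site_statistics(geno_f).to_csv(out / "site_statistics.csv", index=False)
    ld_decay(geno_f).to_csv(out / "ld_decay.csv", index=False)
    coords, _ = mds_ibs(geno_f)
    coords.to_csv(out / "mds_coordinates.csv")
    write_dosage_tsv(geno_f, out / "genotypes_filtered.tsv")
    G = grm_vanraden(geno_f.dosages, geno_f.sample_ids)
    G.to_csv(out / "kernel_G.csv", out / "kernel_G.json")

    # --------------------------------------------------------------- micro QC
    O = None
    if needs_micro and asv is not None:
        asv_f, sample_log = filter_samples(asv)
        asv_f, feature_log = filter_sparse_asvs(asv_f, config.prevalence_min)
        rare = rarefy(asv_f, seed=config.seed)
        transformed = log_center_scale(
            rare, rarefaction_depth=int(rare.library_sizes.min()),
            seed=config.seed)
        alpha_diversity(rare).to_csv(out / "alpha_diversity.csv")
        sample_log.to_csv(out / "removed_samples.tsv", sep="\t", index=False)
        feature_log.to_csv(out / "removed_features.tsv", sep="\t", index=False)
        transformed.values.to_csv(out / "asv_transformed.tsv", sep="\t")
        O = microbial_similarity(transformed.sample_matrix, transformed.sample_ids)
        O.to_csv(out / "kernel_O.csv", out / "kernel_O.json")

    # -------------------------------------------------------------- phenotypes
    phenos, removal_log = derive_phenotypes(growth, config.outlier_sd)
    phenos.to_csv(out / "phenotypes.csv")
    removal_log.to_csv(out / "outlier_removals.tsv", sep="\t", index=False)
    descriptive_statistics(phenos).to_csv(out / "descriptive_statistics.csv")
    r, p = phenotypic_correlations(phenos)
    r.to_csv(out / "phenotypic_correlations_r.csv")
    p.to_csv(out / "phenotypic_correlations_p.csv")

    traits = config.traits or [t for t in TRAITS if t in phenos.columns]

    # ------------------------------------------------------------------- fits
    fits: dict[str, dict] = {}
    n_nonconverged = 0
    rows = []
    for trait in traits:
        y = phenos[trait]
        cells = {"trait": trait, "h2": None, "h2_bar": None,
                 "m2": None, "m2_bar": None}
        fits[trait] = {}
        model_kernels = {"gblup": [G], "mblup": [O], "mgblup": [G, O]}
        for model in ("gblup", "mblup", "mgblup"):
            if model not in config.models:
                continue
            ks = model_kernels[model]
            if any(k is None for k in ks):
                continue
            try:
                res = KernelMixedModel(y, ks).fit()
            except Exception as exc:  # isolate per-fit failures
                log.warning("fit %s/%s failed: %s", trait, model, exc)
                fits[trait][model] = {"error": str(exc)}
                n_nonconverged += 1
                continue
            ratios = derive_ratios(res, n_draws=2000, seed=config.seed)
            record = {
                "converged": res.converged,
                "n_iter": res.n_iter,
                "reason": res.reason,
                "loglik": res.llf,
                "sigma2": dict(zip(res.estimate.labels,
                                   map(float, res.estimate.sigma2))),
            }
            if ratios is not None:
                record["ratios"] = {
                    k: {"estimate": float(v["estimate"]), "se": float(v["se"])}
                    for k, v in ratios.iterrows()
                }
                for name in ratios.index:
                    if name in cells:
                        cells[name] = float(ratios.loc[name, "estimate"])
            else:
                n_nonconverged += 1
            fits[trait][model] = record
        rows.append(cells)

    ratio_table = pd.DataFrame(rows).set_index("trait")
    display = ratio_table.apply(lambda col: col.map(_dash))
    display.to_csv(out / "variance_ratios.csv")

    # -------------------------------------------------------------- bivariate
    rg_matrix = None
    if "bivariate" in config.models and config.bivariate_pairs:
        names = sorted({t for pair in config.bivariate_pairs for t in pair},
                       key=traits.index)
        rg_matrix = pd.DataFrame("", index=names, columns=names)
        for t1, t2 in config.bivariate_pairs:
            try:
                res = BivariateKernelModel(phenos[t1], phenos[t2], G).fit()
                if res.converged:
                    i, j = sorted([t1, t2], key=names.index)
                    rg_matrix.loc[j, i] = f"{res.rg:.3f}"
                    rg_matrix.loc[i, j] = (
                        f"{res.monte_carlo_se(2000, config.seed):.3f}")
                else:
                    n_nonconverged += 1
                    rg_matrix.loc[t2, t1] = "—"
                fits.setdefault("bivariate", {})[f"{t1}:{t2}"] = {
                    "converged": res.converged,
                    "rg": res.rg,
                    "sigma2": dict(zip(res.params.index,
                                       map(float, res.params))),
                }
            except Exception as exc:
                log.warning("bivariate %s-%s failed: %s", t1, t2, exc)
                fits.setdefault("bivariate", {})[f"{t1}:{t2}"] = {
                    "error": str(exc)}
                n_nonconverged += 1
        rg_matrix.to_csv(out / "genetic_correlations.csv")

    with open(out / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=1, default=float)
    manifest["n_nonconverged"] = n_nonconverged
    manifest["traits"] = traits
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineResult(out, ratio_table, rg_matrix, n_nonconverged, manifest)
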