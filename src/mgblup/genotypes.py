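"""SNP genotype container, quality control and genomic summary statistics.

Markers are filtered on call rate, minor allele frequency and a 1-df
chi-square Hardy-Weinberg test; the surviving matrix is completed by
allele-frequency expectation imputation (missing dosage -> 2*p-hat).
Summary statistics cover per-site MAF and nucleotide diversity, binned LD
decay (composite genotypic r-squared) and classical MDS on the
identity-by-state distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "SnpQcReport",
    "GenotypeError",
    "filter_snps",
    "impute_missing",
    "site_statistics",
    "ld_decay",
    "mds_ibs",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP dosage matrix.

    ``dosages`` is float (n_samples, n_markers) with values {0, 1, 2} and
    ``nan`` as the missing sentinel.  ``markers`` carries id, chromosome and
    1-based position; positions are nondecreasing within a chromosome.
    """

    sample_ids: list[str]
    markers: pd.DataFrame  # columns: id, chrom, pos
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.markers):
            raise GenotypeError("dosage shape does not match ids/markers")
        obs = self.dosages[~np.isnan(self.dosages)]
        # raw calls are {0,1,2}; expectation-imputed dosages may be fractional
        if obs.size and ((obs < 0) | (obs > 2)).any():
            raise GenotypeError("dosages must lie in [0, 2] or be missing")
        for _, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise GenotypeError("positions must be nondecreasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def take_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.markers.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
        )


@dataclass
class SnpQcReport:
    """Per-marker QC metrics with pass/fail flags and a summary."""

    table: pd.DataFrame  # id, call_rate, maf, hwe_p, keep, reason
    thresholds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.table["keep"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["keep"]).sum())

    def summary(self) -> pd.Series:
        kept = self.table[self.table["keep"]]
        return pd.Series(
            {
                "n_input": len(self.table),
                "n_retained": self.n_retained,
                "maf_mean": kept["maf"].mean(),
                "maf_sd": kept["maf"].std(),
            }
        )


def _marker_stats(dosages: np.ndarray):
    """Call rate, allele frequency and genotype counts per marker."""
    miss = np.isnan(dosages)
    n_obs = (~miss).sum(axis=0).astype(float)
    call_rate = n_obs / dosages.shape[0]
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosages, axis=0) / np.where(n_obs > 0, 2.0 * n_obs, np.nan)
    counts = np.stack(
        [(dosages == g).sum(axis=0) for g in (0.0, 1.0, 2.0)], axis=0
    ).astype(float)
    return call_rate, p, n_obs, counts


def hwe_chisq_p(counts: np.ndarray, n_obs: np.ndarray) -> np.ndarray:
    """1-df chi-square HWE test from genotype counts (3, m) vs HWE expectation.

    Monomorphic or unobserved markers get p = 1 (no evidence of deviation).
    """
    n0, n1, n2 = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n_obs)
        q = 1.0 - p
        exp = np.stack([n_obs * q**2, 2.0 * n_obs * p * q, n_obs * p**2])
        chi2 = np.nansum((counts - exp) ** 2 / np.where(exp > 0, exp, np.nan), axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | ~np.isfinite(p)
    pval[mono] = 1.0
    return pval


def filter_snps(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.9,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-8,
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Jointly apply call-rate, MAF and HWE thresholds in one pass.

    A marker failing several thresholds reports every reason (comma joined).
    Removing all markers is a hard error.
    """
    if geno.n_samples < 2:
        raise GenotypeError("need at least 2 samples for SNP QC")
    call_rate, p, n_obs, counts = _marker_stats(geno.dosages)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isfinite(maf), maf, 0.0)
    hwe_p = hwe_chisq_p(counts, n_obs)

    fail_cr = call_rate < call_rate_min
    fail_maf = maf < maf_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_cr | fail_maf | fail_hwe)

    reasons = []
    for cr, mf, hw in zip(fail_cr, fail_maf, fail_hwe):
        r = [tag for tag, bad in (("call_rate", cr), ("maf", mf), ("hwe", hw)) if bad]
        reasons.append(",".join(r))
    report = SnpQcReport(
        pd.DataFrame(
            {
                "id": geno.markers["id"].to_numpy(),
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "keep": keep,
                "reason": reasons,
            }
        ),
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
        },
    )
    if not keep.any():
        raise GenotypeError(
            f"all {geno.n_markers} markers removed by QC "
            f"(call rate<{call_rate_min}, MAF<{maf_min}, HWE p<{hwe_p_min})"
        )
    return geno.take_markers(keep), report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean 2*p-hat.

    This preserves each marker's expected dosage; LD-aware phasing is not
    attempted.  A marker with no observed genotype at all is an error.
    """
    d = geno.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return GenotypeMatrix(list(geno.sample_ids), geno.markers.copy(), d)
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = geno.markers["id"].to_numpy()[n_obs == 0]
        raise GenotypeError(f"markers with all genotypes missing: {list(bad[:5])}")
    mean_dosage = np.nansum(d, axis=0) / n_obs
    d[miss] = np.broadcast_to(mean_dosage, d.shape)[miss]
    return GenotypeMatrix(list(geno.sample_ids), geno.markers.copy(), d)


def site_statistics(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF and nucleotide diversity for a complete matrix.

    pi = n_chr/(n_chr - 1) * 2 p (1-p) with n_chr = 2 * n_samples, the
    unbiased per-site heterozygosity convention of standard VCF statistics
    tools.
    """
    if np.isnan(geno.dosages).any():
        raise GenotypeError("site statistics require a complete matrix")
    n_chr = 2.0 * geno.n_samples
    p = geno.dosages.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    pi = (n_chr / (n_chr - 1.0)) * 2.0 * p * (1.0 - p)
    return pd.DataFrame(
        {"id": geno.markers["id"].to_numpy(), "maf": maf, "pi": pi}
    )


def ld_decay(
    geno: GenotypeMatrix,
    max_dist_bp: int = 500_000,
    bin_width_bp: int = 10_000,
) -> pd.DataFrame:
    """Mean composite genotypic r-squared binned by physical distance.

    r2 is the squared Pearson correlation of dosage vectors — the standard
    unphased surrogate for gametic LD.  Only same-chromosome pairs within
    ``max_dist_bp`` contribute.  Returns bin left edge, mean r2 and pair count.
    """
    if bin_width_bp <= 0:
        raise GenotypeError("bin width must be positive")
    if np.isnan(geno.dosages).any():
        raise GenotypeError("LD decay requires a complete matrix")
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    for _, sub in geno.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        X = geno.dosages[:, idx]
        sd = X.std(axis=0)
        ok = sd > 0
        for a in range(len(idx)):
            if not ok[a]:
                continue
            # markers are position-sorted: bounded forward window
            hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            js = np.arange(a + 1, hi)
            js = js[ok[js] & (pos[js] > pos[a])]
            if js.size == 0:
                continue
            xa = X[:, a] - X[:, a].mean()
            Xb = X[:, js] - X[:, js].mean(axis=0)
            r = (xa @ Xb) / (np.linalg.norm(xa) * np.linalg.norm(Xb, axis=0))
            b = ((pos[js] - pos[a] - 1) // bin_width_bp).astype(int)
            np.add.at(sums, b, r**2)
            np.add.at(counts, b, 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame(
        {
            "dist_bp": np.arange(n_bins) * bin_width_bp,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def ibs_distance(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise 1 - IBS distance; IBS = mean over markers of 1 - |xi - xj| / 2."""
    if np.isnan(geno.dosages).any():
        raise GenotypeError("IBS distance requires a complete matrix")
    X = geno.dosages
    n, m = X.shape
    # |xi - xj| summed over markers, via the dosage-class decomposition:
    # sum |xi - xj| = sum_g sum_h |g - h| * (#markers with xi=g, xj=h)
    D = np.zeros((n, n))
    ind = [(X == g).astype(float) for g in (0.0, 1.0, 2.0)]
    for g in range(3):
        for h in range(3):
            w = abs(g - h)
            if w:
                D += w * (ind[g] @ ind[h].T)
    return D / (2.0 * m)


def mds_ibs(geno: GenotypeMatrix, n_components: int = 3):
    """Classical MDS (double-centring + eigendecomposition) on 1-IBS distance.

    Returns (coordinates DataFrame indexed by sample id, eigenvalues).
    """
    n = geno.n_samples
    if n < 3:
        raise GenotypeError("MDS needs at least 3 samples")
    if n_components > n - 1:
        raise GenotypeError("n_components must be <= n_samples - 1")
    D = ibs_distance(geno)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:n_components]
    w_top = w[order]
    coords = V[:, order] * np.sqrt(np.maximum(w_top, 0.0))
    df = pd.DataFrame(
        coords,
        index=pd.Index(geno.sample_ids, name="id"),
        columns=[f"C{i+1}" for i in range(n_components)],
    )
    return df, w_top


# ---------------------------------------------------------------------- I/O

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes (GT field) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = var.gt_types.astype(float)  # 0/1/2, 3=missing with gts012
        g[g == 3] = np.nan
        rows.append(g)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if not rows:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(samples, markers, np.array(rows).T)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased minimal VCF (REF=A, ALT=G placeholders)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = geno.markers["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            gts = [
                gt_map.get(geno.dosages[i, j], "./.")
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        geno.dosages.T,
        index=pd.Index(geno.markers["id"], name="id"),
        columns=geno.sample_ids,
    )
    meta = geno.markers.set_index("id")[["chrom", "pos"]]
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    markers = pd.DataFrame(
        {"id": df.index.astype(str), "chrom": df["chrom"], "pos": df["pos"]}
    ).reset_index(drop=True)
    dosages = df.drop(columns=["chrom", "pos"]).to_numpy(float).T
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    return GenotypeMatrix(samples, markers, dosages)
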