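"""ASV count-table processing: filtering, rarefaction, transforms, diversity.

The fixed pipeline order is sample filtering (library size >= mean - 3 SD),
sparse-feature filtering (prevalence >= 10% of samples), rarefaction to a
common depth by subsampling reads without replacement, then a log10(x+1)
transform with per-feature centring and scaling.  The transformed matrix is
the input of the microbial similarity kernel; alpha diversity (observed
features, Chao1, inverse Simpson, Shannon, Camargo evenness) is computed per
sample, by default on the rarefied table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ASVTable",
    "TransformedMicrobiome",
    "MicrobiomeError",
    "filter_samples",
    "filter_sparse_asvs",
    "rarefy",
    "log_center_scale",
    "alpha_diversity",
]

log = logging.getLogger(__name__)


class MicrobiomeError(ValueError):
    pass


@dataclass
class ASVTable:
    """Non-negative integer counts, features x samples."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise MicrobiomeError("ASV counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise MicrobiomeError("ASV counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="#ASV_ID")

    @classmethod
    def from_tsv(cls, path) -> "ASVTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df)


@dataclass
class TransformedMicrobiome:
    """Per-feature centred/scaled log10(x+1) abundances, features x samples."""

    values: pd.DataFrame
    rarefaction_depth: int | None = None
    seed: int | None = None
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def sample_matrix(self) -> np.ndarray:
        """Samples-by-features orientation, the M of the microbial kernel."""
        return self.values.to_numpy().T

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def filter_samples(table: ASVTable) -> tuple[ASVTable, pd.DataFrame]:
    """Drop samples whose library size is below mean - 3 SD (single pass).

    Mean and SD are computed once on the unfiltered library sizes; the
    comparison is strict, so an SD of zero removes nothing.
    """
    if len(table.sample_ids) < 2:
        raise MicrobiomeError("need at least 2 samples")
    sizes = table.library_sizes
    thr = sizes.mean() - 3.0 * sizes.std(ddof=1)
    keep = sizes >= thr
    removed = pd.DataFrame(
        {"sample": sizes.index[~keep], "library_size": sizes[~keep].to_numpy(),
         "threshold": thr}
    )
    if not removed.empty:
        log.info("filter_samples removed %d samples below %.1f",
                 len(removed), thr)
    return ASVTable(table.counts.loc[:, keep[keep].index]), removed


def filter_sparse_asvs(
    table: ASVTable, prevalence_min: float = 0.10
) -> tuple[ASVTable, pd.DataFrame]:
    """Drop features present (count > 0) in fewer than 10% of samples.

    "Present in less than 10%" is strict: a feature in exactly 10% of samples
    is retained.
    """
    n = len(table.sample_ids)
    present = (table.counts > 0).sum(axis=1)
    min_samples = int(np.ceil(prevalence_min * n))
    keep = present >= min_samples
    if not keep.any():
        raise MicrobiomeError("all features removed by the prevalence filter")
    removed = pd.DataFrame(
        {"feature": present.index[~keep], "n_present": present[~keep].to_numpy(),
         "min_samples": min_samples}
    )
    return ASVTable(table.counts.loc[keep]), removed


def rarefy(table: ASVTable, depth: int | None = None, seed: int = 0) -> ASVTable:
    """Subsample every sample to a common depth without replacement.

    ``depth`` defaults to the smallest library size.  Each column is an
    independent multivariate-hypergeometric draw seeded from ``seed``, so
    column sums equal ``depth`` exactly and the draw is reproducible.
    """
    sizes = table.library_sizes
    if depth is None:
        depth = int(sizes.min())
    too_small = sizes[sizes < depth]
    if not too_small.empty:
        raise MicrobiomeError(
            f"depth {depth} exceeds library size of samples: "
            f"{list(too_small.index[:5])}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, col in enumerate(table.counts.to_numpy().T):
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return ASVTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def log_center_scale(
    table: ASVTable,
    rarefaction_depth: int | None = None,
    seed: int | None = None,
) -> TransformedMicrobiome:
    """log10(x+1), then centre and scale each feature to mean 0, SD 1 (n-1).

    Features constant across samples have zero SD and are dropped with a
    warning; they carry no between-sample signal for the kernel.
    """
    logged = np.log10(table.counts.to_numpy(float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    dropped = [f for f, c in zip(table.feature_ids, constant) if c]
    if dropped:
        log.warning("dropping %d constant features before scaling", len(dropped))
    scaled = (logged[~constant] - mean[~constant]) / sd[~constant]
    values = pd.DataFrame(
        scaled,
        index=[f for f, c in zip(table.feature_ids, constant) if not c],
        columns=table.sample_ids,
    )
    return TransformedMicrobiome(values, rarefaction_depth, seed, dropped)


# ------------------------------------------------------------ alpha diversity

def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: S_obs + F1 (F1 - 1) / (2 (F2 + 1))."""
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def chao1_classic(counts: np.ndarray) -> float:
    """Classic Chao1 variant F1^2 / (2 F2); infinite when F2 = 0, F1 > 0."""
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return float("inf")
    return s_obs + f1**2 / (2.0 * f2)


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum p ln p (natural log by default)."""
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def inverse_simpson(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(1.0 / (p**2).sum())


def camargo_evenness(counts: np.ndarray) -> float:
    """Camargo's evenness 1 - sum_{i<j} |p_i - p_j| / S over observed features."""
    p = counts[counts > 0] / counts.sum()
    s = p.size
    if s == 1:
        return 1.0
    diff = np.abs(p[:, None] - p[None, :])
    return float(1.0 - diff[np.triu_indices(s, k=1)].sum() / s)


def alpha_diversity(
    table: ASVTable,
    chao1_variant: str = "bias_corrected",
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """Per-sample alpha diversity metrics from integer counts.

    Returns a DataFrame indexed by sample id with columns observed, chao1,
    inv_simpson, shannon, camargo.  Empty samples yield all-NaN rows.
    """
    chao = chao1 if chao1_variant == "bias_corrected" else chao1_classic
    rows = {}
    for sample in table.sample_ids:
        c = table.counts[sample].to_numpy()
        if c.sum() == 0:
            log.warning("sample %s is empty; metrics set to missing", sample)
            rows[sample] = dict.fromkeys(
                ["observed", "chao1", "inv_simpson", "shannon", "camargo"], np.nan
            )
            continue
        rows[sample] = {
            "observed": int((c > 0).sum()),
            "chao1": chao(c),
            "inv_simpson": inverse_simpson(c),
            "shannon": shannon(c, shannon_base),
            "camargo": camargo_evenness(c),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df
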