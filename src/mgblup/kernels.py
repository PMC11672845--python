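"""Individual-by-individual similarity kernels.

Two kernels drive the mixed models: the genomic relationship matrix

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),   Z = X - 2p  (column-centred dosages)

and the microbial similarity matrix

    O = M M' / (m - 1)

where M holds the log10(x+1)-transformed, per-feature centred and scaled
ASV abundances with samples in rows and the m features in columns.  Both are
(co)variance matrices for individual-level random effects, so they must be
symmetric and positive semi-definite up to numerical error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelMatrix",
    "KernelError",
    "grm_vanraden",
    "microbial_similarity",
    "align_kernels",
]

#: eigenvalue floor below which a kernel is declared non-PSD
PSD_TOL = 1e-8


class KernelError(ValueError):
    """Raised when a kernel violates its structural contract."""


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over a set of individuals.

    Parameters
    ----------
    ids : sample identifiers, one per row/column.
    values : (n, n) symmetric matrix.
    kind : "genomic" or "microbial" (or any descriptive tag).
    meta : construction metadata (marker/feature counts, denominators).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "genomic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KernelError(
                f"kernel shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise KernelError("kernel is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.ids)

    def check_psd(self, tol: float = PSD_TOL) -> None:
        """Raise :class:`KernelError` if any eigenvalue < -tol."""
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -tol:
            raise KernelError(f"kernel has eigenvalue {w.min():.3e} < -{tol:g}")

    def subset(self, ids: list[str]) -> "KernelMatrix":
        """Return the kernel restricted to ``ids`` (in that order)."""
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KernelError(f"ids not in kernel: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return KernelMatrix(list(ids), self.values[np.ix_(idx, idx)],
                            self.kind, dict(self.meta))

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path, meta_path=None) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"kind": self.kind, **self.meta}, fh, indent=1)

    @classmethod
    def from_csv(cls, path, kind: str = "genomic", meta_path=None) -> "KernelMatrix":
        df = pd.read_csv(path, index_col=0)
        meta: dict = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
            kind = meta.pop("kind", kind)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind, meta)


def grm_vanraden(dosages: np.ndarray, ids: list[str]) -> KernelMatrix:
    """Genomic relationship matrix from complete biallelic dosages.

    ``dosages`` is (n_individuals, n_markers) with values in {0, 1, 2}; allele
    frequencies are estimated from the sample itself.  Monomorphic columns
    carry no information: their centred dosages are zero and they are excluded
    from the ``2 * sum p(1-p)`` denominator.
    """
    X = np.asarray(dosages, dtype=float)
    if np.isnan(X).any():
        raise KernelError("dosage matrix contains missing values; impute first")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise KernelError("all markers are monomorphic; GRM undefined")
    Z = X - 2.0 * p
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return KernelMatrix(
        ids, G, "genomic",
        meta={"n_markers": int(poly.sum()), "denominator": float(denom)},
    )


def microbial_similarity(M: np.ndarray, ids: list[str],
                         feature_ids: list[str] | None = None) -> KernelMatrix:
    """Microbial similarity matrix O = M M' / (m - 1).

    ``M`` is (n_samples, m_features): the log-transformed ASV table after
    per-feature centring and scaling, oriented samples-by-features so the
    product is an n x n sample covariance usable as a random-effect kernel.
    """
    M = np.asarray(M, dtype=float)
    m = M.shape[1]
    if m < 2:
        raise KernelError("need at least 2 features for the microbial kernel")
    O = (M @ M.T) / (m - 1)
    O = (O + O.T) / 2.0
    return KernelMatrix(ids, O, "microbial", meta={"n_features": int(m)})


def align_kernels(ids: list[str], *kernels: KernelMatrix) -> tuple[KernelMatrix, ...]:
    """Restrict every kernel to the common ``ids`` order; hard error on mismatch."""
    return tuple(k.subset(list(ids)) for k in kernels)
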