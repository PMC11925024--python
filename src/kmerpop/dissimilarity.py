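"""k-mer dissimilarity statistics: Jaccard, Bray-Curtis, cosine.

Jaccard compares presence/absence of k-mers, Bray-Curtis compares
relative k-mer frequencies, and cosine compares raw count vectors (it is
invariant to uniform rescaling, so per-sample normalization is
immaterial).  All three are dissimilarities in [0, 1]: 0 for identical
samples, 1 for samples sharing no k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .counting import KmerCountTable, apply_threshold

__all__ = [
    "jaccard",
    "bray_curtis",
    "cosine",
    "METRICS",
    "DissimilarityMatrix",
    "pairwise_matrix",
    "population_score",
]


def _clip01(value: float) -> float:
    # dissimilarities are [0, 1] by construction; trim float round-off
    return float(min(max(value, 0.0), 1.0))


def _check_pair(t1: KmerCountTable, t2: KmerCountTable) -> None:
    if t1.k != t2.k:
        raise ValueError(f"tables have different k: {t1.k} vs {t2.k}")


def _aligned_counts(t1: KmerCountTable, t2: KmerCountTable):
    """Count vectors of both tables over the union of their keys."""
    union = np.union1d(t1.keys_array, t2.keys_array)
    c1 = np.zeros(union.size, dtype=np.float64)
    c2 = np.zeros(union.size, dtype=np.float64)
    c1[np.searchsorted(union, t1.keys_array)] = t1.counts_array
    c2[np.searchsorted(union, t2.keys_array)] = t2.counts_array
    return c1, c2


def jaccard(t1: KmerCountTable, t2: KmerCountTable) -> float:
    """1 - |intersection| / |union| of the two key sets."""
    _check_pair(t1, t2)
    if len(t1) == 0 and len(t2) == 0:
        raise ValueError("Jaccard dissimilarity is undefined for two empty tables")
    n_union = np.union1d(t1.keys_array, t2.keys_array).size
    n_inter = np.intersect1d(t1.keys_array, t2.keys_array, assume_unique=True).size
    return _clip01(1.0 - n_inter / n_union)


def bray_curtis(t1: KmerCountTable, t2: KmerCountTable) -> float:
    """1 - sum of elementwise minima of the relative-frequency vectors.

    Counts are normalized per sample before comparison, so the classical
    Bray-Curtis denominator equals 2 exactly.
    """
    _check_pair(t1, t2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("Bray-Curtis dissimilarity is undefined for an empty table")
    c1, c2 = _aligned_counts(t1, t2)
    f1 = c1 / c1.sum()
    f2 = c2 / c2.sum()
    return _clip01(1.0 - np.minimum(f1, f2).sum())


def cosine(t1: KmerCountTable, t2: KmerCountTable) -> float:
    """1 - cosine similarity of the raw count vectors."""
    _check_pair(t1, t2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("cosine dissimilarity is undefined for a zero count vector")
    c1, c2 = _aligned_counts(t1, t2)
    denom = np.linalg.norm(c1) * np.linalg.norm(c2)
    return _clip01(1.0 - np.dot(c1, c2) / denom)


METRICS: dict[str, Callable[[KmerCountTable, KmerCountTable], float]] = {
    "jaccard": jaccard,
    "braycurtis": bray_curtis,
    "cosine": cosine,
}


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity matrix with provenance."""

    ids: list[str]
    values: np.ndarray
    metric: str
    k: int
    threshold: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix must be square and match the id list")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("matrix diagonal must be zero")
        if np.any((v < 0.0) | (v > 1.0)):
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def pairwise_matrix(
    samples: Sequence[KmerCountTable],
    metric: str,
    threshold: int = 0,
    ids: Sequence[str] | None = None,
) -> DissimilarityMatrix:
    """Apply the count threshold to every sample, then the metric to all
    C(n, 2) pairs."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if ids is None:
        ids = [f"sample{i}" for i in range(len(samples))]
    fn = METRICS[metric]
    tables = [apply_threshold(t, threshold) for t in samples]
    n = len(tables)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(tables[i], tables[j])
    return DissimilarityMatrix(list(ids), values, metric, tables[0].k, threshold)


def population_score(matrix: DissimilarityMatrix) -> float:
    """Mean dissimilarity over all sample pairs (upper triangle).

    This is the single-number summary used when one population of n
    samples becomes one point in a diversity-scaling analysis: the
    empirical estimate of the expected pairwise dissimilarity, mirroring
    how nucleotide diversity averages over haplotype pairs.
    """
    iu = np.triu_indices(matrix.n, k=1)
    return float(matrix.values[iu].mean())
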