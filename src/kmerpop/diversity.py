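"""Nucleotide diversity: classical estimators and k-mer-based bounds.

Links the number of k-mers exclusive to one of two samples to the
nucleotide diversity pi of the population they come from.  A single SNP
isolated by more than k non-repetitive bases creates k sample-exclusive
k-mers on each side of a haploid pair (2k total), and the worst case per
pairwise difference depends on ploidy, giving the conversion factor
a(x).  Dividing the summed exclusive-k-mer counts by a(x) and by the
number of haplotype pairs yields a quantity bounded above by pi
(in average-pairwise-difference units) whenever k-mer sets are complete,
error-free and variation is SNP-only.

pi is handled in two unit conventions throughout: a mean pairwise
difference *count* and a *per-site* mean (count / sequence length).  The
k-mer bound is naturally in count units; the neutral-equilibrium
expectation is per site.  Conversions are left to the caller.
"""

from __future__ import annotations

import numpy as np

from ._encode import encode_sequence
from .counting import KmerCountTable

__all__ = [
    "ploidy_factor",
    "symmetric_difference_count",
    "pi_bound_from_kmers",
    "expected_pi_neutral",
    "nei_pi",
    "watterson_theta",
    "true_pi",
    "pairwise_differences",
]


def ploidy_factor(x: int, k: int) -> float:
    """Worst-case sample-exclusive k-mers per pairwise difference, a(x).

    For ploidy 1-3 the maximum arises when two individuals are homozygous
    for different alleles: 2k exclusive k-mers per x**2 pairwise
    differences.  For x >= 4 the maximum instead comes from a SNP on a
    single haplotype: k exclusive k-mers per 2x-1 differences.
    """
    if x < 1:
        raise ValueError("ploidy must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if x <= 3:
        return 2.0 * k / (x * x)
    return k / (2.0 * x - 1.0)


def _key_set(sample):
    if isinstance(sample, KmerCountTable):
        return sample
    return set(sample)


def _kmer_length(sample) -> int | None:
    if isinstance(sample, KmerCountTable):
        return sample.k
    lengths = {len(s) for s in sample}
    if not lengths:
        return None
    if len(lengths) > 1:
        raise ValueError(f"mixed k-mer lengths within one set: {sorted(lengths)}")
    return lengths.pop()


def symmetric_difference_count(set_i, set_j) -> int:
    """Number of k-mers exclusive to one of the two samples.

    Accepts sets of k-mer strings or :class:`KmerCountTable` objects
    (key sets are compared; counts are ignored).
    """
    ki, kj = _kmer_length(set_i), _kmer_length(set_j)
    if ki is not None and kj is not None and ki != kj:
        raise ValueError(f"k-mer lengths differ between sets: {ki} vs {kj}")
    if isinstance(set_i, KmerCountTable) and isinstance(set_j, KmerCountTable):
        return int(np.setxor1d(set_i.keys_array, set_j.keys_array,
                               assume_unique=True).size)
    return len(_key_set(set_i) ^ _key_set(set_j))


def pi_bound_from_kmers(samples, ploidy: int, k: int | None = None) -> float:
    """Lower bound on pi (pairwise-difference units) from k-mer sets.

    Sums the exclusive-k-mer count over all sample pairs and divides by
    a(x) * C(n*x, 2).  Under complete, error-free k-mer sets with
    SNP-only variation the result is <= the average pairwise difference
    count of the underlying haplotypes, with equality for haploid
    samples whose SNPs are isolated by more than k bases.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if k is None:
        for s in samples:
            k = _kmer_length(s)
            if k is not None:
                break
        if k is None:
            raise ValueError("cannot infer k from empty sets; pass k explicitly")
    n = len(samples)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += symmetric_difference_count(samples[i], samples[j])
    m = n * ploidy
    n_pairs = m * (m - 1) // 2
    return total / (ploidy_factor(ploidy, k) * n_pairs)


def expected_pi_neutral(ne: float, mu: float, ploidy: int = 2) -> float:
    """Equilibrium per-site diversity of a neutral population.

    E[pi] = 2x*Ne*mu / (1 + (4/3) * 2x*Ne*mu): linear in the compound
    parameter Ne*mu when small and saturating at 0.75 (the maximum
    per-site heterozygosity of a four-letter alphabet) as it grows.
    """
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    if not 0.0 <= mu < 1.0:
        raise ValueError("mutation rate must lie in [0, 1)")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    t = 2.0 * ploidy * ne * mu
    return t / (1.0 + (4.0 / 3.0) * t)


def nei_pi(allele_freqs, n: int, aggregate: str = "mean"):
    """Nei's diversity from per-locus allele frequency vectors.

    Per locus: (1 - sum(p_i**2)) * n / (n - 1), with n the number of
    sequences sampled.  ``aggregate`` is ``"mean"``, ``"sum"`` or
    ``"none"`` (per-locus array).
    """
    if n < 2:
        raise ValueError("need at least 2 sequences")
    values = []
    for freqs in allele_freqs:
        freqs = np.asarray(freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1: {freqs}")
        values.append((1.0 - np.sum(freqs**2)) * n / (n - 1))
    values = np.asarray(values)
    if aggregate == "mean":
        return float(values.mean())
    if aggregate == "sum":
        return float(values.sum())
    if aggregate == "none":
        return values
    raise ValueError("aggregate must be 'mean', 'sum' or 'none'")


def watterson_theta(s: int, n: int) -> float:
    """Watterson's estimator: segregating sites over the harmonic number."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if s < 0:
        raise ValueError("segregating site count must be >= 0")
    harmonic = np.sum(1.0 / np.arange(1, n))
    return s / harmonic


def _haplotype_matrix(haplotypes) -> np.ndarray:
    if isinstance(haplotypes, np.ndarray):
        return np.atleast_2d(haplotypes)
    arrays = [encode_sequence(h) for h in haplotypes]
    lengths = {a.size for a in arrays}
    if len(lengths) > 1:
        raise ValueError(f"haplotypes have unequal lengths: {sorted(lengths)}")
    return np.vstack(arrays)


def pairwise_differences(haplotypes, ids=None):
    """Per-pair Hamming distance matrix as a labeled DataFrame.

    Suitable for TSV export via ``.to_csv(path, sep="\\t")``.
    """
    import pandas as pd

    mat = _haplotype_matrix(haplotypes)
    m = mat.shape[0]
    if ids is None:
        ids = [f"hap{i}" for i in range(m)]
    out = np.zeros((m, m), dtype=np.int64)
    for i in range(m - 1):
        counts = np.count_nonzero(mat[i + 1 :] != mat[i], axis=1)
        out[i, i + 1 :] = counts
        out[i + 1 :, i] = counts
    return pd.DataFrame(out, index=list(ids), columns=list(ids))


def true_pi(haplotypes) -> tuple[float, float]:
    """Exact mean pairwise Hamming distance of an aligned panel.

    Returns ``(count, per_site)``: the mean over all C(m, 2) haplotype
    pairs of the number of differing sites, and that mean divided by the
    sequence length.
    """
    mat = _haplotype_matrix(haplotypes)
    m, length = mat.shape
    if m < 2:
        raise ValueError("need at least 2 haplotypes")
    total = 0
    for i in range(m - 1):
        total += int(np.count_nonzero(mat[i + 1 :] != mat[i]))
    n_pairs = m * (m - 1) // 2
    count = total / n_pairs
    return count, count / length
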