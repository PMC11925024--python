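"""Canonical k-mer counting, thresholding, and frequency spectra.

A :class:`KmerCountTable` maps canonical k-mer strings to counts.  For
k <= 32 the table is backed by sorted 2-bit packed uint64 codes, so
counting reads and joining tables stays vectorized; longer k-mers fall
back to plain string keys.  Either way the table behaves as a
``Mapping[str, int]`` and absent k-mers implicitly have count 0 (the
full 4**k count vector is never materialized).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from typing import Iterable, Iterator

import numpy as np

from ._encode import (
    MAX_PACKED_K,
    decode_codes,
    encode_kmer,
    encode_sequence,
    reverse_complement,
    window_codes,
)

__all__ = [
    "KmerCountTable",
    "canonicalize",
    "count_kmers",
    "apply_threshold",
    "to_frequencies",
    "spectrum",
]

_ACGT = frozenset("ACGT")


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Raises ``ValueError`` on ambiguous bases so callers can skip the
    offending window.
    """
    kmer = kmer.upper()
    if not _ACGT.issuperset(kmer):
        raise ValueError(f"k-mer contains non-ACGT bases: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


class KmerCountTable(Mapping):
    """Sparse map from k-mer string to positive count for one sample.

    Iteration order is the sorted key order.  ``keys_array`` /
    ``counts_array`` expose the parallel sorted backing arrays for
    vectorized set algebra; keys are packed uint64 codes when
    k <= 32 and plain strings otherwise.
    """

    __slots__ = ("k", "canonical", "_keys", "_counts")

    def __init__(self, k: int, keys: np.ndarray, counts: np.ndarray, canonical: bool = True):
        self.k = int(k)
        self.canonical = bool(canonical)
        self._keys = keys
        self._counts = counts

    # -- construction --------------------------------------------------

    @classmethod
    def empty(cls, k: int, canonical: bool = True) -> "KmerCountTable":
        dtype = np.uint64 if k <= MAX_PACKED_K else object
        return cls(k, np.empty(0, dtype=dtype), np.empty(0, dtype=np.int64), canonical)

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], k: int | None = None,
                  canonical: bool = True) -> "KmerCountTable":
        if not counts:
            if k is None:
                raise ValueError("k is required for an empty table")
            return cls.empty(k, canonical)
        kmers = list(counts)
        if k is None:
            k = len(kmers[0])
        for kmer, c in counts.items():
            if len(kmer) != k:
                raise ValueError(f"mixed k-mer lengths: {kmer!r} is not a {k}-mer")
            if canonical and canonicalize(kmer) != kmer:
                raise ValueError(f"key is not in canonical form: {kmer!r}")
            if c < 1:
                raise ValueError(f"counts must be >= 1, got {c} for {kmer!r}")
        if k <= MAX_PACKED_K:
            keys = np.fromiter(
                (encode_kmer(s, k, canonical=False) for s in kmers),
                dtype=np.uint64, count=len(kmers),
            )
        else:
            keys = np.array(kmers, dtype=object)
        vals = np.fromiter((counts[s] for s in kmers), dtype=np.int64, count=len(kmers))
        order = np.argsort(keys, kind="stable")
        return cls(k, keys[order], vals[order], canonical)

    # -- Mapping interface ---------------------------------------------

    def __len__(self) -> int:
        return int(self._keys.size)

    def __iter__(self) -> Iterator[str]:
        if self._keys.dtype == object:
            yield from self._keys
        else:
            yield from decode_codes(self._keys, self.k)

    def _key_of(self, kmer: str):
        if len(kmer) != self.k:
            raise KeyError(kmer)
        key = canonicalize(kmer) if self.canonical else kmer.upper()
        if self._keys.dtype == object:
            return key
        return np.uint64(encode_kmer(key, self.k, canonical=False))

    def __getitem__(self, kmer: str) -> int:
        key = self._key_of(kmer)
        idx = np.searchsorted(self._keys, key)
        if idx < len(self._keys) and self._keys[idx] == key:
            return int(self._counts[idx])
        raise KeyError(kmer)

    def __contains__(self, kmer) -> bool:
        try:
            self[kmer]
        except (KeyError, ValueError):
            return False
        return True

    # -- array views and summaries ---------------------------------------

    @property
    def keys_array(self) -> np.ndarray:
        return self._keys

    @property
    def counts_array(self) -> np.ndarray:
        return self._counts

    def total(self) -> int:
        """Total number of k-mer instances (sum of counts)."""
        return int(self._counts.sum())

    def to_dict(self) -> dict[str, int]:
        return dict(zip(iter(self), (int(c) for c in self._counts)))

    def __repr__(self) -> str:
        return (f"KmerCountTable(k={self.k}, distinct={len(self)}, "
                f"total={self.total()}, canonical={self.canonical})")


def _iter_code_arrays(sequences, k: int, canonical: bool) -> Iterator[np.ndarray]:
    """Yield packed window-code arrays for heterogeneous sequence input."""
    if isinstance(sequences, str):
        sequences = [sequences]
    if hasattr(sequences, "reads"):  # ReadSet duck type
        sequences = sequences.reads
    if isinstance(sequences, np.ndarray):
        yield window_codes(sequences, k, canonical)
        return
    # group equal-length string/array inputs into batches for one
    # vectorized pass per length
    batches: dict[int, list[np.ndarray]] = {}
    for seq in sequences:
        arr = encode_sequence(seq)
        batches.setdefault(arr.size, []).append(arr)
    for length, group in batches.items():
        if length < k:
            continue
        yield window_codes(np.vstack(group), k, canonical)


def count_kmers(sequences, k: int, canonical: bool = True) -> KmerCountTable:
    """Count k-mers in sequences by sliding a width-k window.

    ``sequences`` may be a string, an iterable of strings, a uint8
    base-code array (1-D, or 2-D with one row per read), or a
    :class:`~kmerpop.simulate.ReadSet`.  Windows containing ambiguous
    bases are skipped.  With ``canonical=True`` each window is counted
    under the lexicographic minimum of itself and its reverse
    complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= MAX_PACKED_K:
        parts = list(_iter_code_arrays(sequences, k, canonical))
        if not parts:
            return KmerCountTable.empty(k, canonical)
        codes = parts[0] if len(parts) == 1 else np.concatenate(parts)
        if codes.size == 0:
            return KmerCountTable.empty(k, canonical)
        keys, counts = np.unique(codes, return_counts=True)
        return KmerCountTable(k, keys, counts.astype(np.int64), canonical)
    return _count_kmers_long(sequences, k, canonical)


def _count_kmers_long(sequences, k: int, canonical: bool) -> KmerCountTable:
    # string fallback for k > 32; adequate for occasional long-k use
    if isinstance(sequences, str):
        sequences = [sequences]
    if hasattr(sequences, "sequences"):
        sequences = sequences.sequences()
    counter: Counter[str] = Counter()
    for seq in sequences:
        if isinstance(seq, np.ndarray):
            from ._encode import decode_matrix

            seq = decode_matrix(seq)[0]
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            try:
                counter[canonicalize(window) if canonical else window] += 1
            except ValueError:
                continue  # ambiguous base: skip window
    if not counter:
        return KmerCountTable.empty(k, canonical)
    keys = np.array(sorted(counter), dtype=object)
    counts = np.fromiter((counter[s] for s in keys), dtype=np.int64, count=keys.size)
    return KmerCountTable(k, keys, counts, canonical)


def apply_threshold(table: KmerCountTable, t: int) -> KmerCountTable:
    """Drop every k-mer whose count is below ``t`` (counts >= t survive).

    Error k-mers from sequencing mostly occur once or twice, so a small
    threshold removes them before any dissimilarity computation.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    if t <= 1:
        return table
    keep = table.counts_array >= t
    return KmerCountTable(table.k, table.keys_array[keep],
                          table.counts_array[keep], table.canonical)


def to_frequencies(table: KmerCountTable) -> dict[str, float]:
    """Counts normalized to relative frequencies summing to 1."""
    total = table.total()
    if total == 0:
        raise ValueError("cannot normalize an empty count table")
    return dict(zip(iter(table), table.counts_array / total))


def spectrum(table: KmerCountTable) -> dict[int, int]:
    """k-mer frequency spectrum: multiplicity -> number of distinct k-mers."""
    if len(table) == 0:
        return {}
    values, reps = np.unique(table.counts_array, return_counts=True)
    return {int(v): int(r) for v, r in zip(values, reps)}
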