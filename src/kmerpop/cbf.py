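"""Counting bloom filters: fixed-size compressed k-mer count vectors.

A counting bloom filter (CBF) maps each k-mer to ``h`` positions of an
``m``-element array of saturating 16-bit counters via double hashing and
adds the k-mer's count at every position.  Distinct k-mers may collide,
but as long as two samples share (m, h, seed) their collisions are
consistent, so cosine dissimilarity computed on the counter arrays
tracks the dissimilarity of the raw count vectors.  Collisions merge
mass and therefore bias dissimilarity downward, never upward on average;
a larger m or more hash functions reduce the effect.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._encode import MAX_PACKED_K, encode_kmer, hash_pair_codes, hash_pair_str
from .counting import KmerCountTable

__all__ = [
    "CountingBloomFilter",
    "hash_positions",
    "compress",
    "cosine_cbf",
    "save_cbf",
    "load_cbf",
]

COUNTER_MAX = 65535  # unsigned 16-bit ceiling; additions saturate here

_MAGIC = b"KCBF"


@dataclass
class CountingBloomFilter:
    m: int
    h: int
    seed: int
    counters: np.ndarray  # uint16, length m

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("array length m must be >= 1")
        if self.h < 1:
            raise ValueError("number of hash functions h must be >= 1")
        self.counters = np.asarray(self.counters, dtype=np.uint16)
        if self.counters.shape != (self.m,):
            raise ValueError("counter array length must equal m")

    @property
    def params(self) -> tuple[int, int, int]:
        return (self.m, self.h, self.seed)

    def total(self) -> int:
        return int(self.counters.sum(dtype=np.int64))

    def write_tsv(self, path) -> None:
        """Debug export: position and counter value of non-zero cells."""
        with open(path, "w") as fh:
            fh.write(f"#m={self.m} h={self.h} seed={self.seed}\n")
            for pos in np.flatnonzero(self.counters):
                fh.write(f"{pos}\t{self.counters[pos]}\n")


def _base_hashes(keys: np.ndarray, seed: int):
    if keys.dtype == object:  # string keys (k > 32)
        pairs = [hash_pair_str(kmer, seed) for kmer in keys]
        a = np.array([p[0] for p in pairs], dtype=np.uint64)
        b = np.array([p[1] for p in pairs], dtype=np.uint64)
        return a, b
    return hash_pair_codes(keys, seed)


def hash_positions(kmer, m: int, h: int, seed: int) -> np.ndarray:
    """The h array positions of one k-mer, by double hashing.

    position_i = (h_a(kmer) + i * h_b(kmer)) mod m for i = 0..h-1.
    ``kmer`` may be a string or a packed uint64 code.
    """
    if isinstance(kmer, str):
        if len(kmer) <= MAX_PACKED_K:
            key = np.array([encode_kmer(kmer, len(kmer), canonical=False)],
                           dtype=np.uint64)
        else:
            key = np.array([kmer], dtype=object)
    else:
        key = np.array([kmer], dtype=np.uint64)
    a, b = _base_hashes(key, seed)
    i = np.arange(h, dtype=np.uint64)
    with np.errstate(over="ignore"):
        return ((a[0] + i * b[0]) % np.uint64(m)).astype(np.int64)


def compress(table: KmerCountTable, m: int = 10_000, h: int = 2,
             seed: int = 0) -> CountingBloomFilter:
    """Compress a count table into a counting bloom filter.

    Every k-mer's count is added at each of its h positions; counters
    saturate at 65535 instead of wrapping.  Without saturation the
    counter total equals h times the table's total count.
    """
    if m < 1:
        raise ValueError("array length m must be >= 1")
    if h < 1:
        raise ValueError("number of hash functions h must be >= 1")
    acc = np.zeros(m, dtype=np.int64)
    if len(table) > 0:
        a, b = _base_hashes(table.keys_array, seed)
        counts = table.counts_array
        with np.errstate(over="ignore"):
            for i in range(h):
                pos = ((a + np.uint64(i) * b) % np.uint64(m)).astype(np.int64)
                np.add.at(acc, pos, counts)
    counters = np.minimum(acc, COUNTER_MAX).astype(np.uint16)
    return CountingBloomFilter(m, h, seed, counters)


def cosine_cbf(f1: CountingBloomFilter, f2: CountingBloomFilter) -> float:
    """Cosine dissimilarity of two counter arrays.

    The filters must share (m, h, seed) so that hash collisions are
    consistent between samples.
    """
    if f1.params != f2.params:
        raise ValueError(
            f"incomparable filters: params {f1.params} vs {f2.params}"
        )
    c1 = f1.counters.astype(np.float64)
    c2 = f2.counters.astype(np.float64)
    denom = np.linalg.norm(c1) * np.linalg.norm(c2)
    if denom == 0.0:
        raise ValueError("cosine dissimilarity is undefined for an all-zero filter")
    return float(min(max(1.0 - np.dot(c1, c2) / denom, 0.0), 1.0))


def save_cbf(cbf: CountingBloomFilter, path) -> None:
    """Binary layout: 16-byte header (magic, m, h, seed as little-endian
    32-bit fields) followed by m little-endian 16-bit counters."""
    path = Path(path)
    header = _MAGIC + struct.pack("<III", cbf.m, cbf.h, cbf.seed)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(cbf.counters.astype("<u2").tobytes())
    except OSError as exc:
        raise OSError(f"failed to write filter to {path}: {exc}") from exc


def load_cbf(path) -> CountingBloomFilter:
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(16)
        if len(header) != 16 or header[:4] != _MAGIC:
            raise ValueError(f"{path}: not a counting-bloom-filter file")
        m, h, seed = struct.unpack("<III", header[4:])
        counters = np.frombuffer(fh.read(2 * m), dtype="<u2")
        if counters.size != m:
            raise ValueError(f"{path}: truncated counter array")
    return CountingBloomFilter(m, h, seed, counters.astype(np.uint16))
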