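"""Two-bit sequence encoding and integer hashing utilities (internal).

Everything in this module works on numpy arrays of base codes
(A=0, C=1, G=2, T=3; any value >= 4 marks an ambiguous base) so that
k-mer extraction, canonicalization and hashing stay vectorized.  The
code order matches alphabetical base order, so comparisons on packed
integers agree with lexicographic comparisons on k-mer strings.
"""

from __future__ import annotations

import hashlib

import numpy as np

#: longest k-mer that fits a single 64-bit packed code
MAX_PACKED_K = 32

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq) -> np.ndarray:
    """Encode a DNA string (or pass through a uint8 code array)."""
    if isinstance(seq, np.ndarray):
        if seq.dtype != np.uint8:
            raise TypeError("encoded sequences must be uint8 base codes")
        return seq
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Decode a (n, L) uint8 code matrix into a list of strings."""
    mat = np.atleast_2d(mat)
    letters = _LETTERS[mat]
    return [row.tobytes().decode("ascii") for row in letters]


def pack_windows(vals: np.ndarray, k: int):
    """Packed codes of every length-k window of ``vals``.

    ``vals`` is a 1-D array or a 2-D array of equal-length rows.  Returns
    ``(fwd, rc, valid)``: forward and reverse-complement packed codes of
    shape (rows, L-k+1) and a boolean mask of windows free of ambiguous
    bases (``None`` when every window is clean).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_PACKED_K:
        raise ValueError(f"packed windows support k <= {MAX_PACKED_K}")
    vals = np.atleast_2d(vals)
    n, length = vals.shape
    w = length - k + 1
    if w <= 0:
        empty = np.empty((n, 0), dtype=np.uint64)
        return empty, empty, None

    bad = vals > 3
    any_bad = bool(bad.any())
    safe = np.where(bad, 0, vals).astype(np.uint64) if any_bad else vals.astype(np.uint64)

    fwd = np.zeros((n, w), dtype=np.uint64)
    rc = np.zeros((n, w), dtype=np.uint64)
    three = np.uint64(3)
    two = np.uint64(2)
    for j in range(k):
        col = safe[:, j : j + w]
        fwd = (fwd << two) | col
        rc |= (three - col) << np.uint64(2 * j)

    valid = None
    if any_bad:
        csum = np.zeros((n, length + 1), dtype=np.int64)
        np.cumsum(bad, axis=1, out=csum[:, 1:])
        valid = (csum[:, k:] - csum[:, :w]) == 0
    return fwd, rc, valid


def window_codes(vals: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """Flat array of packed codes for all valid windows of ``vals``."""
    fwd, rc, valid = pack_windows(vals, k)
    codes = np.minimum(fwd, rc) if canonical else fwd
    if valid is not None:
        return codes[valid]
    return codes.ravel()


def encode_kmer(kmer: str, k: int, canonical: bool) -> int:
    """Packed code of a single k-mer string (k <= 32)."""
    if len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {kmer!r}")
    codes = window_codes(encode_sequence(kmer), k, canonical)
    if codes.size != 1:
        raise ValueError(f"k-mer contains ambiguous bases: {kmer!r}")
    return int(codes[0])


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 codes back into k-mer strings."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    work = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for j in range(k - 1, -1, -1):
        out[:, j] = (work & three).astype(np.uint8)
        work >>= two
    return decode_matrix(out)


# -- hashing ---------------------------------------------------------------

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_SEED_SALT_B = np.uint64(0x6A09E667F3BCC909)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = x + _SM_GAMMA
    x = (x ^ (x >> np.uint64(30))) * _SM_M1
    x = (x ^ (x >> np.uint64(27))) * _SM_M2
    return x ^ (x >> np.uint64(31))


def hash_pair_codes(codes: np.ndarray, seed: int):
    """Two independent 64-bit hashes per packed k-mer code (vectorized)."""
    codes = np.atleast_1d(np.asarray(codes, dtype=np.uint64))
    with np.errstate(over="ignore"):
        sa = _splitmix64(np.asarray([seed], dtype=np.uint64))[0]
        sb = _splitmix64(np.asarray([seed], dtype=np.uint64) ^ _SEED_SALT_B)[0]
        return _splitmix64(codes ^ sa), _splitmix64(codes ^ sb)


def hash_pair_str(kmer: str, seed: int):
    """Two 64-bit hashes of a k-mer string via keyed blake2b (any k)."""
    key = (seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
    digest = hashlib.blake2b(kmer.encode("ascii"), digest_size=16, key=key).digest()
    return (
        int.from_bytes(digest[:8], "little"),
        int.from_bytes(digest[8:], "little"),
    )
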