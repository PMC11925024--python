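"""Chance k-mer matching between random genomes and minimum-k selection.

Models two genomes as i.i.d. draws from (possibly different) base
compositions and asks: what is the probability that a random k-mer drawn
from one composition occurs, forward or as a reverse complement, in a
genome of length L drawn from the other?  Solving the complementary
probability for k gives the minimum k-mer length at which shared k-mers
between two genomes are unlikely to be coincidental — the usual starting
point for choosing k in alignment-free comparisons.

All probabilities are evaluated in log space so that genome lengths up
to 1e10 and k up to a few hundred stay well conditioned: the per-window
match probability sigma**k reaches the 1e-60 scale long before k = 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._encode import pack_windows

__all__ = [
    "BaseComposition",
    "sigma_forward",
    "sigma_reverse",
    "prob_chance_match",
    "marginal_chance_match",
    "min_k",
    "MinKResult",
    "monte_carlo_match",
    "MonteCarloResult",
]

_TOL = 1e-12


@dataclass(frozen=True)
class BaseComposition:
    """Per-base sampling probabilities of a multinomial genome model."""

    pa: float
    pt: float
    pg: float
    pc: float

    def __post_init__(self) -> None:
        probs = (self.pa, self.pt, self.pg, self.pc)
        if any(p < 0.0 or p > 1.0 for p in probs):
            raise ValueError(f"base probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > _TOL:
            raise ValueError(f"base probabilities must sum to 1: {probs}")

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_gc(cls, gc: float) -> "BaseComposition":
        """AT/GC-symmetric composition with the given GC fraction."""
        if not 0.0 <= gc <= 1.0:
            raise ValueError("GC fraction must lie in [0, 1]")
        at = (1.0 - gc) / 2.0
        return cls(at, at, gc / 2.0, gc / 2.0)

    def as_acgt_array(self) -> np.ndarray:
        """Probabilities in code order A, C, G, T (for samplers)."""
        return np.array([self.pa, self.pc, self.pg, self.pt], dtype=float)


def sigma_forward(comp1: BaseComposition, comp2: BaseComposition | None = None) -> float:
    """Probability that one position drawn from each composition matches."""
    c2 = comp1 if comp2 is None else comp2
    return comp1.pa * c2.pa + comp1.pt * c2.pt + comp1.pg * c2.pg + comp1.pc * c2.pc


def sigma_reverse(comp1: BaseComposition, comp2: BaseComposition | None = None) -> float:
    """Probability that one position from each composition matches as a
    reverse-complement pair (A-T, T-A, G-C, C-G)."""
    c2 = comp1 if comp2 is None else comp2
    return comp1.pa * c2.pt + comp1.pt * c2.pa + comp1.pg * c2.pc + comp1.pc * c2.pg


def _sigma(comp1, comp2, strand: str) -> float:
    if strand == "forward":
        return sigma_forward(comp1, comp2)
    if strand == "reverse":
        return sigma_reverse(comp1, comp2)
    raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")


def prob_chance_match(
    k: int,
    L: float,
    comp1: BaseComposition,
    comp2: BaseComposition | None = None,
    *,
    strand: str = "forward",
    exact: bool = True,
) -> float:
    """Probability that a random k-mer occurs at least once in a random
    genome of length L.

    With ``exact=True`` the k-mer is tested at all L-k+1 windows, giving
    1 - (1 - sigma**k)**(L-k+1); with ``exact=False`` the k << L
    approximation 1 - (1 - sigma**k)**L is used.  ``strand`` selects the
    forward-match or reverse-complement-match probability.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    if exact and k > L:
        raise ValueError(f"exact mode requires k <= L (k={k}, L={L})")
    sigma = _sigma(comp1, comp2, strand)
    if sigma >= 1.0:
        return 1.0
    if sigma <= 0.0:
        return 0.0
    log_sigma_k = k * math.log(sigma)
    sigma_k = math.exp(log_sigma_k)
    if sigma_k >= 1.0:
        return 1.0
    windows = (L - k + 1) if exact else L
    return -math.expm1(windows * math.log1p(-sigma_k))


def marginal_chance_match(
    k: int,
    L: float,
    comp1: BaseComposition,
    comp2: BaseComposition | None = None,
    *,
    strand: str = "forward",
    exact: bool = True,
) -> float:
    """Chance-match probability marginalized over the random k-mer.

    The closed forms in :func:`prob_chance_match` plug the *mean*
    per-position match probability sigma into the occurrence formula,
    which by Jensen's inequality is an upper bound on the true
    probability E_K[1 - (1 - p(K))**W]: a low-complexity k-mer drawn from
    a skewed composition matches far more often than an average one, and
    the occurrence probability is concave in p(K).  This function
    computes the marginal exactly by enumerating k-mer base-composition
    classes (p(K) depends only on the base counts of K), still assuming
    match events at different windows are independent.  For uniform
    compositions p(K) is constant and the two functions agree.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if exact and k > L:
        raise ValueError(f"exact mode requires k <= L (k={k}, L={L})")
    c2 = comp1 if comp2 is None else comp2
    if strand == "forward":
        genome_probs = comp1.as_acgt_array()
    elif strand == "reverse":
        # genome letter must equal the complement of the k-mer letter
        genome_probs = comp1.as_acgt_array()[::-1].copy()  # T, G, C, A
    else:
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    kmer_probs = c2.as_acgt_array()
    windows = (L - k + 1) if exact else L

    total = 0.0
    for na in range(k + 1):
        for nc in range(k + 1 - na):
            for ng in range(k + 1 - na - nc):
                nt = k - na - nc - ng
                counts = (na, nc, ng, nt)
                weight = (
                    math.comb(k, na)
                    * math.comb(k - na, nc)
                    * math.comb(k - na - nc, ng)
                )
                prob_class = weight * math.prod(
                    p**n for p, n in zip(kmer_probs, counts) if n
                )
                if prob_class == 0.0:
                    continue
                p_match = math.prod(
                    p**n for p, n in zip(genome_probs, counts) if n
                )
                if p_match >= 1.0:
                    occurs = 1.0
                elif p_match <= 0.0:
                    occurs = 0.0
                else:
                    occurs = -math.expm1(windows * math.log1p(-p_match))
                total += prob_class * occurs
    return min(total, 1.0)


class MinKResult(NamedTuple):
    """Minimum k on each strand and their maximum (the recommended k)."""

    k_forward: int
    k_reverse: int
    k: int


def _min_k_strand(sigma: float, L: float, q: float) -> int:
    if sigma >= 1.0:
        raise ValueError(
            "degenerate composition: per-position match probability is 1, "
            "no finite k achieves the requested chance-match probability"
        )
    if sigma <= 0.0:
        return 1
    # 1 - (1-q)**(1/L), evaluated stably for q/L down to ~1e-300
    target = -math.expm1(math.log1p(-q) / L)
    k = math.ceil(math.log(target) / math.log(sigma))
    return max(1, k)


def min_k(
    L: float,
    q: float,
    comp1: BaseComposition,
    comp2: BaseComposition | None = None,
) -> MinKResult:
    """Minimum k-mer length achieving chance-match probability <= q.

    Applies the ceiling formula k = ceil(log_sigma(1 - (1-q)**(1/L)))
    independently for forward and reverse-complement matching and
    returns both along with their maximum.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    kf = _min_k_strand(sigma_forward(comp1, comp2), L, q)
    kr = _min_k_strand(sigma_reverse(comp1, comp2), L, q)
    return MinKResult(kf, kr, max(kf, kr))


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical chance-match tallies from simulated genome/k-mer pairs."""

    forward_hits: int
    reverse_hits: int
    trials: int

    @property
    def p_forward(self) -> float:
        return self.forward_hits / self.trials

    @property
    def p_reverse(self) -> float:
        return self.reverse_hits / self.trials


def monte_carlo_match(
    comp: BaseComposition,
    k: int,
    L: int,
    trials: int,
    seed: int | None = None,
    *,
    chunk: int = 256,
) -> MonteCarloResult:
    """Empirically estimate the chance-match probability.

    Each trial draws a genome of length L and a k-mer, both i.i.d. from
    ``comp``, and records whether the k-mer occurs in the genome text
    (forward tally) and whether its reverse complement does (reverse
    tally).  The genome is treated as single-stranded text.  Results are
    deterministic given ``seed``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if k > L:
        raise ValueError(f"k must not exceed L (k={k}, L={L})")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(comp.as_acgt_array())
    cum[-1] = 1.0  # guard against round-off

    def draw(shape) -> np.ndarray:
        return np.searchsorted(cum, rng.random(shape), side="right").astype(np.uint8)

    fwd_hits = 0
    rev_hits = 0
    done = 0
    while done < trials:
        n = min(chunk, trials - done)
        genomes = draw((n, L))
        kmers = draw((n, k))
        kf, kr, _ = pack_windows(kmers, k)  # one window per row
        windows, _, _ = pack_windows(genomes, k)
        fwd_hits += int(np.any(windows == kf, axis=1).sum())
        rev_hits += int(np.any(windows == kr, axis=1).sum())
        done += n
    return MonteCarloResult(fwd_hits, rev_hits, trials)
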