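"""Neutral population panels with known diversity, and simulated reads.

The generator produces the inputs for diversity-scaling studies without
any external data.  A panel is built in three steps:

1. a random reference of length L with a configurable GC fraction
   (bases i.i.d.);
2. a neutral coalescent genealogy for n individuals of ploidy x, sampled
   with msprime (single non-recombining locus);
3. infinite-sites mutations dropped on the branches at a per-site rate
   chosen so that the expected per-site pairwise diversity equals the
   requested ``theta``; every mutation gets a distinct site and a derived
   base drawn uniformly from the three non-ancestral nucleotides.

The resulting haplotypes carry an *exact* true diversity pi_t (computed
by brute-force pairwise comparison, not from the model expectation),
which is what k-mer dissimilarity scores are later regressed against.

Reads are sampled uniformly along each haplotype with round-robin
allocation across an individual's x haplotypes, random strand, and
independent per-base substitution errors at a fixed rate — a deliberately
plain error process whose single parameter feeds the count-threshold
filter downstream.  No indels, no quality-dependent error profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from ._encode import decode_matrix
from .diversity import true_pi
from .io import write_fasta, write_fastq

__all__ = [
    "HaplotypePanel",
    "ReadSet",
    "simulate_panel",
    "simulate_reads",
    "write_panel",
    "write_reads",
]

#: fraction of sites that may segregate before the infinite-sites
#: placement is refused as over-saturated
_MAX_SITE_FRACTION = 0.8


@dataclass
class HaplotypePanel:
    """A sampled neutral population with exact true diversity."""

    reference: np.ndarray          # (L,) uint8 base codes
    haplotypes: np.ndarray         # (n*x, L) uint8 base codes
    individuals: list[list[int]]   # haplotype row indices per individual
    positions: np.ndarray          # sorted segregating-site positions
    ploidy: int
    theta: float
    gc: float
    seed: int | None
    pi_count: float = field(init=False)
    pi_per_site: float = field(init=False)

    def __post_init__(self) -> None:
        self.pi_count, self.pi_per_site = true_pi(self.haplotypes)

    @property
    def length(self) -> int:
        return int(self.reference.size)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def individual_haplotypes(self, individual: int) -> np.ndarray:
        return self.haplotypes[self.individuals[individual]]

    def haplotype_strings(self) -> list[str]:
        return decode_matrix(self.haplotypes)

    def reference_string(self) -> str:
        return decode_matrix(self.reference)[0]


@dataclass
class ReadSet:
    """Simulated single-end reads from one individual."""

    reads: np.ndarray              # (n_reads, read_length) uint8 base codes
    individual: int
    coverage: float
    read_length: int
    error_rate: float
    haplotype_index: np.ndarray    # source haplotype row per read
    starts: np.ndarray             # 0-based start position per read
    reverse: np.ndarray            # True where the read is reverse-strand

    @property
    def n_reads(self) -> int:
        return int(self.reads.shape[0])

    @property
    def total_bases(self) -> int:
        return int(self.reads.size)

    @property
    def quality_char(self) -> str:
        """Phred symbol matching the substitution error rate."""
        if self.error_rate <= 0.0:
            phred = 40
        else:
            phred = int(round(-10.0 * math.log10(self.error_rate)))
        return chr(min(max(phred, 2), 40) + 33)

    def sequences(self) -> list[str]:
        return decode_matrix(self.reads)


def _random_reference(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = np.array([at, gc / 2.0, gc / 2.0, at])  # A, C, G, T
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(length), side="right").astype(np.uint8)


def simulate_panel(
    L: int,
    n: int,
    ploidy: int = 2,
    theta: float = 0.01,
    gc: float = 0.36,
    seed: int | None = None,
) -> HaplotypePanel:
    """Simulate a neutral panel of n individuals with expected per-site
    diversity ``theta``.

    ``theta`` is the target E[pi] per site; the realized pi_t of any one
    panel varies around it with the (large) coalescent variance of a
    single non-recombining genealogy.  The default GC fraction of 0.36
    mimics a gene-rich plant chromosome segment.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0.0 <= theta < 0.75:
        raise ValueError(
            "theta must lie in [0, 0.75): per-site diversity cannot exceed "
            "the four-letter maximum of 0.75"
        )
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    reference = _random_reference(rng, L, gc)
    m = n * ploidy

    # Genealogy time scaling: with population_size = 1/2 and ploidy x,
    # the expected path length between two haplotypes is x generations,
    # so a per-site branch mutation rate of theta/x yields E[pi] = theta.
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n, ploidy=ploidy, population_size=0.5, random_seed=ms_seed
    )
    tree = ts.first()

    mu = theta / ploidy
    mutated_nodes: list[int] = []
    for node in tree.nodes():
        if tree.parent(node) == -1:
            continue
        n_mut = rng.poisson(tree.branch_length(node) * mu * L)
        mutated_nodes.extend([node] * int(n_mut))

    total_mutations = len(mutated_nodes)
    if total_mutations > _MAX_SITE_FRACTION * L:
        raise ValueError(
            f"drew {total_mutations} mutations for {L} sites; theta={theta} "
            f"is too high for infinite-sites placement at this length"
        )

    haplotypes = np.tile(reference, (m, 1))
    if total_mutations:
        # distinct sites for every mutation: the infinite-sites model
        positions = rng.choice(L, size=total_mutations, replace=False)
        shifts = rng.integers(1, 4, size=total_mutations).astype(np.uint8)
        for node, pos, shift in zip(mutated_nodes, positions, shifts):
            derived = (reference[pos] + shift) % 4
            carriers = list(tree.samples(node))
            haplotypes[carriers, pos] = derived
        positions = np.sort(positions)
    else:
        positions = np.empty(0, dtype=np.int64)

    individuals = [list(ind.nodes) for ind in ts.individuals()]
    return HaplotypePanel(
        reference=reference,
        haplotypes=haplotypes,
        individuals=individuals,
        positions=positions,
        ploidy=ploidy,
        theta=theta,
        gc=gc,
        seed=seed,
    )


def simulate_reads(
    panel: HaplotypePanel,
    individual: int,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int | None = None,
) -> ReadSet:
    """Simulate uniform-coverage single-end reads from one individual.

    Read count = round(coverage * x * L / read_length), allocated
    round-robin across the individual's x haplotypes so each haplotype
    is covered at the nominal depth.  Start positions are uniform,
    strands random, and each base is substituted independently with
    probability ``error_rate``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= individual < panel.n_individuals:
        raise ValueError(f"no individual {individual} in this panel")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    L = panel.length
    if read_length < 1 or read_length > L:
        raise ValueError(f"read_length must lie in [1, {L}]")

    rng = np.random.default_rng(seed)
    x = panel.ploidy
    n_reads = int(round(coverage * x * L / read_length))
    if n_reads < 1:
        raise ValueError("requested coverage yields zero reads")
    hap_rows = panel.individuals[individual]
    per_hap = np.full(x, n_reads // x, dtype=np.int64)
    per_hap[: n_reads % x] += 1

    offsets = np.arange(read_length)
    read_blocks = []
    hap_index = []
    start_blocks = []
    for row, count in zip(hap_rows, per_hap):
        starts = rng.integers(0, L - read_length + 1, size=count)
        read_blocks.append(panel.haplotypes[row][starts[:, None] + offsets])
        hap_index.append(np.full(count, row, dtype=np.int64))
        start_blocks.append(starts)
    reads = np.vstack(read_blocks)
    hap_index = np.concatenate(hap_index)
    starts = np.concatenate(start_blocks)

    reverse = rng.random(n_reads) < 0.5
    reads[reverse] = 3 - reads[reverse, ::-1]

    if error_rate > 0.0:
        err = rng.random(reads.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            shifts = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads[err] = (reads[err] + shifts) % 4

    return ReadSet(
        reads=reads,
        individual=individual,
        coverage=coverage,
        read_length=read_length,
        error_rate=error_rate,
        haplotype_index=hap_index,
        starts=starts,
        reverse=reverse,
    )


def write_panel(panel: HaplotypePanel, fasta_path, reference_path=None,
                metadata_path=None) -> None:
    """Write haplotypes (and optionally the reference and a metadata
    sidecar TSV with parameters, pi_t and segregating-site positions)."""
    names = []
    for ind, rows in enumerate(panel.individuals):
        for a, _row in enumerate(rows):
            names.append(f"ind{ind}_hap{a}")
    write_fasta(zip(names, panel.haplotype_strings()), fasta_path)
    if reference_path is not None:
        write_fasta([("reference", panel.reference_string())], reference_path)
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        try:
            with open(metadata_path, "w") as fh:
                fh.write("field\tvalue\n")
                fh.write(f"L\t{panel.length}\n")
                fh.write(f"n_individuals\t{panel.n_individuals}\n")
                fh.write(f"ploidy\t{panel.ploidy}\n")
                fh.write(f"theta\t{panel.theta}\n")
                fh.write(f"gc\t{panel.gc}\n")
                fh.write(f"seed\t{panel.seed}\n")
                fh.write(f"pi_count\t{panel.pi_count}\n")
                fh.write(f"pi_per_site\t{panel.pi_per_site}\n")
                fh.write(f"n_segregating\t{panel.positions.size}\n")
                fh.write(
                    "positions\t" + ",".join(str(p) for p in panel.positions) + "\n"
                )
        except OSError as exc:
            raise OSError(f"failed to write metadata to {metadata_path}: {exc}") from exc


def write_reads(readset: ReadSet, path) -> None:
    """Write a read set as FASTQ with a constant quality encoding the
    error rate's Phred equivalent."""
    qual = readset.quality_char * readset.read_length
    names = (
        f"ind{readset.individual}_read{i}" for i in range(readset.n_reads)
    )
    write_fastq(
        ((name, seq, qual) for name, seq in zip(names, readset.sequences())),
        path,
    )
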