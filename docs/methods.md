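# Methods

This note records the models implemented in kmerpop, the conventions and
parameter defaults, and what the synthetic data can and cannot say about
real sequencing experiments.

## Chance-match theory

Two genomes are modeled as i.i.d. multinomial draws over {A, C, G, T}
with compositions (p_A, p_T, p_G, p_C); a k-mer K is drawn from the
second composition and tested against all L−k+1 windows of the first
genome. With Σ_F = Σᵢ p_i¹p_i² (forward) and Σ_R = p_A¹p_T² + p_T¹p_A² +
p_G¹p_C² + p_C¹p_G² (reverse complement), the closed forms are

    P(K occurs) = 1 − (1 − Σᵏ)^(L−k+1)      (exact window count)
                ≈ 1 − (1 − Σᵏ)^L            (k ≪ L approximation)

and the minimum k for a tolerated probability q is
k = ⌈log_Σ(1 − (1−q)^{1/L})⌉ per strand, taking the maximum of the two.

Three caveats, all reflected in the tests:

* **The closed forms are upper bounds.** They plug the *mean*
  per-position probability Σ into a formula that is concave in the
  per-k-mer probability p(K) = Πⱼ p_{K_j}, so by Jensen's inequality
  they overestimate the marginal P = E_K[1 − (1 − p(K))^W]. The gap is
  zero for uniform composition and grows with skew (at GC 21%, k = 8,
  L = 10 kb: bound 0.79 vs true 0.53). `marginal_chance_match`
  computes the marginal exactly by enumerating k-mer base-composition
  classes (C(k+3, 3) classes, trivial for k ≤ 60); the Monte-Carlo
  verifier is validated against it, and the closed forms are validated
  as one-sided bounds. For choosing a *minimum* k a conservative bound
  errs in the safe direction.
* **Window dependence is ignored.** Matches at overlapping windows are
  treated as independent. The Monte-Carlo agreement (within 3 binomial
  SE at 10⁴ trials across compositions from uniform to GC 21%) shows the
  residual effect is below sampling noise at L = 10 kb.
* **The exact/approximate gap is ≈ (k−1)/L relative** in the small-p
  regime (the forms differ by k−1 windows in the exponent), so the
  approximation is excellent for genome-scale L but visibly off at, say,
  k = 10, L = 10⁵ (≈10⁻⁴ relative). Both forms are exposed; probabilities
  are evaluated via `expm1`/`log1p` in log space so that Σᵏ down to
  10⁻³⁰⁰ and L up to 10¹⁰ remain well conditioned.

The minimum-k ceiling formula is applied literally. Note that it is the
probability, not the formula, that reproduces round-number tolerances:
a 19-mer against a 3 Gb uniform genome gives 1.09%, i.e. "1%" at the
printed precision, while the ceiling formula for q = 1% exactly would
return k = 20.

## k-mer sharing and nucleotide diversity

For individuals i, j of ploidy x with complete, error-free k-mer sets
and SNP-only variation, each pairwise difference creates at most a(x)
sample-exclusive k-mers, where

    a(x) = 2k/x²      for 1 ≤ x ≤ 3   (maximized by opposite homozygotes)
    a(x) = k/(2x−1)   for x ≥ 4       (maximized by a single-haplotype SNP)

Summing |K_i ∪ K_j| − |K_i ∩ K_j| over sample pairs and dividing by
a(x)·C(nx, 2) gives a statistic that never exceeds the average pairwise
difference count π, with equality for haploid pairs whose SNPs are
isolated by more than k bases. SNPs closer than k together, mutations
recreating k-mers present elsewhere, and shared heterozygosity all push
the statistic below π — it is a certificate of *at least* this much
diversity, not an estimator.

π is reported in two unit conventions: a mean pairwise difference
*count* (the natural unit of the k-mer bound) and a *per-site* mean
(count divided by sequence length, the unit of the neutral expectation
E[π] = 2xN_eμ/(1 + (4/3)·2xN_eμ), which saturates at 0.75 — the maximum
per-site heterozygosity of a four-letter alphabet). The two are related
by the locus length; the caller converts explicitly, since mixing them
silently is the easiest way to misread the bound.

C(nx, 2) counts all haplotype pairs including within-individual pairs,
matching the "n times ploidy, choose 2" convention of the bound's
derivation, and `true_pi` averages Hamming distances over the same set
of pairs.

## Counting and dissimilarity conventions

* Canonical form = lexicographic minimum of a k-mer and its reverse
  complement (alphabet order A < C < G < T). Internally k-mers of
  length ≤ 32 are packed two bits per base into uint64 keys whose
  numeric order equals lexicographic order; longer k-mers fall back to
  string keys. Windows containing non-ACGT bases are skipped.
* Count tables are sparse; the 4ᵏ-dimensional count vector is implicit
  (absent k-mer = count 0). Tests verify sparse metrics against dense
  4ᵏ vectors for small k.
* Thresholding (drop counts < t, default t = 5) happens before any
  normalization or dissimilarity computation. Error k-mers concentrate
  at multiplicities 1–2 while true k-mers cluster near the per-haplotype
  coverage, so a small threshold separates them cleanly at ≥10×.
* Bray–Curtis is computed on per-sample relative frequencies (its
  denominator is then exactly 2); cosine on raw counts (scale-invariant
  anyway); Jaccard on key sets. A population's score is the mean over
  all C(n, 2) individual-pair dissimilarities — the empirical estimate
  of the expected pairwise dissimilarity, mirroring π's definition as a
  mean over haplotype pairs. Other poolings are possible; the mean is
  the exposed default.

Note the count-based metrics have a noise floor: even identical genomes
sequenced twice differ in k-mer multiplicities, giving Bray–Curtis
≈ 0.5·E|Δc|/E[c] (≈0.1 at 10–30× coverage) at zero diversity. This
floor is an intercept, not a slope, and cancels in comparisons across
populations sequenced alike.

## Counting bloom filter

An m-element array of unsigned 16-bit counters; each k-mer maps to h
positions by double hashing (pos_i = (h_a + i·h_b) mod m, with h_a, h_b
from a seeded splitmix64 mix of the packed k-mer, or keyed blake2b for
k > 32) and its count is added at every position, saturating at 65535
rather than wrapping. Absent saturation, Σ counters = h · Σ counts.

Defaults m = 10,000 and h = 2. Two samples are comparable only if they
share (m, h, seed): collisions then merge the *same* k-mers in both
arrays, so compression shrinks cosine dissimilarity (merged mass looks
shared) but preserves the ordering of populations by diversity. Raising
h or m reduces the shrinkage; at m far above the distinct-k-mer count
the compressed cosine equals the raw-count cosine exactly (each count
simply appears h times in the vector).

## Synthetic data

`simulate_panel` generates a study population in three steps: a random
reference with configurable GC (default 0.36, a gene-rich plant
chromosome value); a single-locus neutral coalescent genealogy for n·x
haplotypes sampled with msprime (no recombination); and infinite-sites
mutations dropped on branches with Poisson counts, every mutation at a
distinct site, derived base uniform over the three alternatives. The
parameter `theta` is the target E[π] per site: with msprime
`population_size = 1/2` and ploidy x, the expected inter-haplotype path
length is x generations, so a per-site branch mutation rate of θ/x gives
E[π] = θ (verified empirically to within Monte-Carlo error over 300
replicates). The panel records its *realized* π_t by brute-force
pairwise comparison, and that realized value — not θ — is the regressor
in all downstream analyses. θ is validated against the 0.75 per-site
ceiling and against infinite-sites saturation of the locus.

`simulate_reads` draws single-end reads of fixed length (default 150 bp)
with uniform starts, round-robin allocation over the individual's x
haplotypes (read count = coverage·x·L/read_length, so each haplotype is
covered at the nominal depth), random strand, and independent per-base
substitution errors (default 0.1%). FASTQ output encodes the error
rate's Phred equivalent as a constant quality.

What this generator does *not* emulate: recombination (a single
genealogy per locus inflates the between-panel variance of tree-shape
statistics), indels and structural variation, position- and
quality-dependent Illumina error profiles, GC-coverage bias, and paired
ends. Consequently passing tests demonstrate the statistical machinery
— not robustness to real-data artifacts. One visible consequence of
uniform read starts on a linear sequence: the first and last read-length
of each haplotype is under-covered, so a few terminal k-mers are missed
at any finite coverage (real libraries share this edge effect;
tests assert interior-k-mer recovery).

## The scaling experiment

`scaling_experiment_config` fixes the standard sweep: 40 diversity
levels (30 target-π values linearly spanning 0.0008–0.025, where the
score–π relation is near-linear, plus 10 spanning 0.03–0.1 to expose the
plateau), panels of 10 diploids over 20 kb, 150 bp reads at 30× with
0.1% error, count threshold 5, Bray–Curtis at k = 30 and cosine at
k = 10 (raw and CBF-compressed, m = 10⁴, h = 2). One replicate per
level; every stage's seed derives deterministically from the master seed
via `numpy.random.SeedSequence` spawn keys, so a config and a seed
reproduce the record table bit for bit. The sweep takes ~2 minutes on
one CPU.

Ordinary least squares of population score on realized per-site π_t
(points with π_t ≤ 0.025) quantifies the score–diversity relationship;
R² is reported from `scipy.stats.linregress`. At k = 30 the relation
plateaus above π ≈ 2.5% — one SNP can alter up to 2k k-mers, so at high
diversity nearly all k-mers already differ — and `plateau_check`
reports the high/low slope ratio (≈0.02 at these settings). Shorter
k-mers (k = 10) stay monotone to π = 0.1 at the cost of low-π
sensitivity. At this 20 kb scale the Bray–Curtis k = 30 regression
yields R² ≈ 0.90–0.94 and the cosine k = 10 regressions ≈ 0.84–0.93
depending on the master seed; the residual scatter is dominated by the
per-panel fluctuation of the count-noise floor, which shrinks as
1/√(number of k-mers) and is therefore ~√5 smaller for a 100 kb locus,
where the same pipeline approaches R² ≈ 0.97. The raw-count and
CBF-compressed cosine regressions give nearly identical fits (R²
difference 0.01–0.035 across seeds) and the compressed scores preserve
the raw ranking essentially perfectly (Spearman rank correlation
> 0.998) — compression costs score magnitude, not diversity
information.

## Numerical and degenerate-input conventions

* Dissimilarities are clipped to [0, 1] after computation (float
  round-off can produce −2⁻⁵² on identical inputs); matrices validate
  symmetry, zero diagonal and range on construction.
* Metrics on empty tables (or zero-norm vectors) raise rather than
  return a conventional value; regression with fewer than 3 points or
  zero variance raises likewise.
* `min_k` with a degenerate composition (Σ ≥ 1) raises — no finite k
  exists; Σ = 0 (e.g. pure-A vs pure-C reverse matching) returns k = 1.
* Seeds: every public simulation function takes an explicit seed;
  msprime seeds are derived from the numpy generator so one integer
  reproduces everything. Derived seeds stay below 2³¹.
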