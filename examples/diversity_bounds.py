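"""Relating k-mer sharing to nucleotide diversity.

Builds a small neutral panel, computes the exclusive-k-mer bound on pi
for its individuals, and compares with the exact diversity and with the
neutral-equilibrium expectation.
"""

from kmerpop import (
    count_kmers,
    expected_pi_neutral,
    pi_bound_from_kmers,
    simulate_panel,
    true_pi,
)

panel = simulate_panel(L=10_000, n=5, ploidy=2, theta=0.004, seed=7)
print(f"panel: {panel.n_individuals} diploids, "
      f"{panel.positions.size} segregating sites")
print(f"true pi: {panel.pi_count:.2f} pairwise differences "
      f"({panel.pi_per_site:.5f} per site)")

# per-individual k-mer sets (both haplotypes pooled), k = 31
k = 31
sets = [set(count_kmers(panel.individual_haplotypes(i), k))
        for i in range(panel.n_individuals)]
bound = pi_bound_from_kmers(sets, ploidy=2, k=k)
print(f"k-mer bound on pi: {bound:.2f} (never exceeds the true {panel.pi_count:.2f};"
      " close SNPs and shared heterozygous sites keep it below)")

# the neutral-equilibrium expectation saturates at 0.75 per site
for ne_mu in (1e-4, 1e-2, 1.0, 1e4):
    print(f"Ne*mu = {ne_mu:.0e}: E[pi per site] = "
          f"{expected_pi_neutral(1e8, ne_mu / 1e8, ploidy=2):.4f}")
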