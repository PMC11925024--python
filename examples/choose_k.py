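"""How long must k be before shared k-mers imply shared ancestry?

Computes the chance-match probability for a k-mer drawn from one random
genome against another, the minimum k achieving a tolerated probability,
and verifies the formulas by simulation.
"""

from kmerpop import (
    BaseComposition,
    marginal_chance_match,
    min_k,
    monte_carlo_match,
    prob_chance_match,
)

# two genomes, both GC-poor (21% GC), each 10 Gb long
comp = BaseComposition.from_gc(0.21)
result = min_k(L=1e10, q=1e-6, comp1=comp)
print(f"minimum k (forward {result.k_forward}, reverse {result.k_reverse}): {result.k}")
# -> 34: below this, a random 10 Gb genome likely shares k-mers with
#    another by base composition alone; at or above it the chance is <= 1e-6.

for k in (19, 25, 34):
    p = prob_chance_match(k, 1e10, comp, exact=False)
    print(f"k={k}: chance-match probability {p:.3g}")

# Monte-Carlo check at desk scale: 10 kb genomes, 2000 trials
k, L = 8, 10_000
mc = monte_carlo_match(comp, k=k, L=L, trials=2000, seed=42)
marginal = marginal_chance_match(k, L, comp, exact=True)
closed = prob_chance_match(k, L, comp, exact=True)
print(f"\nempirical P(8-mer in 10 kb genome) = {mc.p_forward:.3f}")
print(f"exact marginal over k-mers = {marginal:.3f}, "
      f"closed-form sigma^k bound = {closed:.3f}")
# the empirical hit fraction matches the exact marginalization; the
# closed form overshoots for skewed compositions (it is a conservative
# upper bound, exact only for uniform base composition)
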