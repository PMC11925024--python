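"""Chance-match probabilities, minimum-k selection, Monte-Carlo verifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerpop import (
    BaseComposition,
    marginal_chance_match,
    min_k,
    monte_carlo_match,
    prob_chance_match,
    sigma_forward,
    sigma_reverse,
)

UNIFORM = BaseComposition.uniform()
GC42 = BaseComposition.from_gc(0.42)
GC21 = BaseComposition.from_gc(0.21)


compositions = st.builds(
    lambda raw: BaseComposition(*(raw / raw.sum())),
    st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4).map(np.array),
)


class TestSigma:
    @pytest.mark.parametrize(
        "comp1, comp2, expected",
        [
            (UNIFORM, None, 0.25),
            (GC42, GC42, 0.2564),
            (BaseComposition(1, 0, 0, 0), None, 1.0),
        ],
    )
    def test_forward_values(self, comp1, comp2, expected):
        assert sigma_forward(comp1, comp2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "comp1, comp2, expected",
        [
            (BaseComposition(1, 0, 0, 0), None, 0.0),
            (UNIFORM, None, 0.25),
        ],
    )
    def test_reverse_values(self, comp1, comp2, expected):
        assert sigma_reverse(comp1, comp2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("gc", [0.0, 0.21, 0.42, 0.5, 0.8, 1.0])
    def test_at_gc_symmetric_composition_strands_agree(self, gc):
        comp = BaseComposition.from_gc(gc)
        assert sigma_forward(comp) == pytest.approx(sigma_reverse(comp), abs=1e-15)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            BaseComposition(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            BaseComposition(-0.1, 0.5, 0.3, 0.3)


class TestProbChanceMatch:
    def test_19mer_in_3gb_uniform_rounds_to_one_percent(self):
        p = max(
            prob_chance_match(19, 3e9, UNIFORM, strand=s, exact=False)
            for s in ("forward", "reverse")
        )
        assert round(p * 100) == 1

    def test_27mer_in_10gb_gc42_rounds_to_1e6(self):
        p = max(
            prob_chance_match(27, 1e10, GC42, strand=s, exact=False)
            for s in ("forward", "reverse")
        )
        # one significant figure
        exponent = math.floor(math.log10(p))
        assert round(p / 10**exponent) * 10**exponent == pytest.approx(1e-6)

    def test_long_kmers_vanish(self):
        assert prob_chance_match(500, 1e10, UNIFORM, exact=False) < 1e-12

    def test_approximate_form_matches_high_precision_evaluation(self):
        import sympy

        expected = float(
            1 - (1 - sympy.Rational(1, 4) ** 8) ** 10_000
        )  # exponent L: the k << L approximation
        got = prob_chance_match(8, 10_000, UNIFORM, exact=False)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_k_and_L(self):
        for comp in (UNIFORM, GC42, GC21):
            probs_k = [prob_chance_match(k, 1e6, comp) for k in range(2, 25)]
            assert all(a >= b for a, b in zip(probs_k, probs_k[1:]))
            probs_l = [prob_chance_match(12, L, comp) for L in (1e3, 1e5, 1e7, 1e9)]
            assert all(a <= b for a, b in zip(probs_l, probs_l[1:]))

    @pytest.mark.parametrize("k,L", [(5, 5000), (8, 10_000), (10, 100_000)])
    def test_exact_and_approximate_agree_for_small_k_over_L(self, k, L):
        # the forms differ by k-1 windows in the exponent, so the relative
        # gap is bounded by (k-1) * sigma**k * (1-p)/p — tiny when k << L
        for comp in (UNIFORM, GC42):
            exact = prob_chance_match(k, L, comp, exact=True)
            approx = prob_chance_match(k, L, comp, exact=False)
            assert approx >= exact
            sig_k = sigma_forward(comp) ** k
            bound = (k - 1) * sig_k * (1 - exact) / exact
            assert (approx - exact) / exact <= bound * 1.01 + 1e-15

    def test_forms_agree_to_1e6_at_genome_scale(self):
        exact = prob_chance_match(19, 3e9, UNIFORM, exact=True)
        approx = prob_chance_match(19, 3e9, UNIFORM, exact=False)
        assert approx == pytest.approx(exact, rel=1e-6)

    def test_degenerate_sigma_one_gives_probability_one(self):
        comp = BaseComposition(1, 0, 0, 0)
        assert prob_chance_match(10, 100, comp, strand="forward") == 1.0
        assert prob_chance_match(10, 100, comp, strand="reverse") == 0.0

    def test_exact_mode_requires_k_at_most_L(self):
        with pytest.raises(ValueError):
            prob_chance_match(11, 10, UNIFORM, exact=True)


class TestMarginalChanceMatch:
    @pytest.mark.parametrize("k,L", [(4, 500), (8, 10_000)])
    def test_equals_closed_form_for_uniform_composition(self, k, L):
        for strand in ("forward", "reverse"):
            assert marginal_chance_match(
                k, L, UNIFORM, strand=strand
            ) == pytest.approx(prob_chance_match(k, L, UNIFORM, strand=strand),
                               rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(comp=compositions, k=st.integers(2, 12))
    def test_closed_form_is_an_upper_bound(self, comp, k):
        for strand in ("forward", "reverse"):
            marginal = marginal_chance_match(k, 10_000, comp, strand=strand)
            closed = prob_chance_match(k, 10_000, comp, strand=strand)
            assert closed >= marginal - 1e-12

    def test_two_mer_brute_force_enumeration(self):
        """All 16 possible 2-mers enumerated explicitly."""
        comp = GC21
        L, k = 50, 2
        probs = dict(zip("ACGT", comp.as_acgt_array()))
        total = 0.0
        for a in "ACGT":
            for b in "ACGT":
                p_draw = probs[a] * probs[b]
                p_match = probs[a] * probs[b]
                total += p_draw * (1 - (1 - p_match) ** (L - k + 1))
        assert marginal_chance_match(k, L, comp) == pytest.approx(total, rel=1e-12)


class TestMinK:
    def test_gc21_10gb_q1e6_needs_34(self):
        assert min_k(1e10, 1e-6, GC21).k == 34

    def test_single_base_genome(self):
        assert min_k(1, 0.5, UNIFORM).k == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        comp=compositions,
        L=st.floats(10, 1e8),
        q=st.floats(1e-9, 0.5),
    )
    def test_result_is_smallest_k_meeting_q(self, comp, L, q):
        """Ceiling-formula output scanned against the probability curve."""
        result = min_k(L, q, comp)
        for strand, k_strand in (("forward", result.k_forward),
                                 ("reverse", result.k_reverse)):
            assert prob_chance_match(k_strand, L, comp, strand=strand,
                                     exact=False) <= q * (1 + 1e-9)
            if k_strand > 1:
                assert prob_chance_match(k_strand - 1, L, comp, strand=strand,
                                         exact=False) > q * (1 - 1e-9)

    def test_degenerate_composition_has_no_finite_k(self):
        with pytest.raises(ValueError):
            min_k(1e6, 1e-3, BaseComposition(1, 0, 0, 0))

    def test_q_bounds_validated(self):
        with pytest.raises(ValueError):
            min_k(1e6, 0.0, UNIFORM)
        with pytest.raises(ValueError):
            min_k(1e6, 1.0, UNIFORM)


class TestMonteCarlo:
    def test_single_base_kmer_almost_surely_present(self):
        mc = monte_carlo_match(UNIFORM, 1, 10_000, 1000, seed=7)
        assert mc.p_forward >= 0.999

    def test_same_seed_reproduces_tallies(self):
        a = monte_carlo_match(GC42, 4, 300, 200, seed=42)
        b = monte_carlo_match(GC42, 4, 300, 200, seed=42)
        assert (a.forward_hits, a.reverse_hits) == (b.forward_hits, b.reverse_hits)

    def test_matches_exact_theory_within_three_binomial_se(self):
        k, L, trials = 8, 10_000, 10_000
        mc = monte_carlo_match(UNIFORM, k, L, trials, seed=5)
        p = prob_chance_match(k, L, UNIFORM, exact=True)
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(mc.p_forward - p) <= 3 * se
        p_r = prob_chance_match(k, L, UNIFORM, strand="reverse", exact=True)
        assert abs(mc.p_reverse - p_r) <= 3 * se

    def test_kmer_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_match(UNIFORM, 50, 10, 10, seed=0)
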