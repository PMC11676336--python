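"""Charged-context densities: hand counts, independent oracles (cycle walk
and sliding-window simulation), UHS property, and bound compliance."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import small_schemes
from minidens import bounds, density, io, schemes
from minidens.combinatorics import enumerate_pure_cycles


def cycle_walk_density(scheme) -> Fraction:
    """Independent exact density: walk every pure cycle of the De Bruijn
    graph whose vertices are contexts, count charged rotations."""
    ell = scheme.window_length + 1
    sigma = scheme.sigma
    charged = 0
    for cyc in enumerate_pure_cycles(sigma, ell):
        walk = cyc.canonical + cyc.canonical  # covers all rotations
        arr = io.as_codes(walk, sigma)
        for i in range(cyc.length):
            ctx = arr[i : i + ell]
            if scheme.rule(ctx[:-1]) != scheme.rule(ctx[1:]) + 1:
                charged += 1
    return Fraction(charged, sigma**ell)


def sliding_window_simulation(scheme, seq) -> int:
    """Independent selection count: scalar sweep tracking picked positions."""
    L = scheme.window_length
    picked = set()
    for i in range(len(seq) - L + 1):
        picked.add(i + scheme.rule(seq[i : i + L]))
    return len(picked)


def test_lexicographic_2_1_2_exact_density():
    lex = schemes.lexicographic_minimizer(2, 1, 2)
    est = density.exact_density(lex)
    assert est.exact_fraction == Fraction(6, 8)
    # coincides with the necklace bound: the bound is tight at k=1
    assert est.exact_fraction == bounds.lower_bound_g(2, 2, 1).value_exact
    assert len(density.charged_contexts_forward(lex)) == 6


def test_constant_zero_scheme_has_density_one():
    sch = schemes.table_scheme(2, 2, 2, [0] * 8)
    assert density.exact_density(sch).exact_fraction == 1
    assert density.exact_density(sch, mode="local").exact_fraction == 1
    seq = io.random_sequence(2, 10_000, seed=0)
    assert density.empirical_density(sch, seq).value == pytest.approx(1.0, abs=1e-3)


def test_w1_local_contexts_all_charged():
    sch = schemes.random_minimizer(1, 3, 2, seed=0)
    assert density.exact_density(sch, mode="local").exact_fraction == 1


@pytest.mark.parametrize("w,k,sigma", [(2, 2, 2), (3, 2, 2)])
def test_exact_density_equals_cycle_walk_oracle(w, k, sigma):
    for sch in small_schemes(w, k, sigma):
        assert density.exact_density(sch).exact_fraction == cycle_walk_density(sch)


@pytest.mark.parametrize("w,k,sigma", [(2, 2, 2), (3, 3, 2), (2, 3, 4)])
def test_select_agrees_with_sliding_window_simulation(w, k, sigma):
    seq = io.random_sequence(sigma, 3_000, seed=17)
    for sch in small_schemes(w, k, sigma):
        assert len(sch.select(seq)) == sliding_window_simulation(sch, seq)


def test_empirical_matches_exact_within_binomial_error(random_dna_1m):
    seq = random_dna_1m[:1_000_000] % 2  # binary sequence
    lex = schemes.lexicographic_minimizer(2, 1, 2)
    est = density.empirical_density(lex, seq)
    assert est.value == pytest.approx(0.75, abs=0.005)
    # 3-sigma binomial agreement for every small scheme
    for sch in small_schemes(3, 2, 2):
        exact = density.exact_density(sch).value
        emp = density.empirical_density(sch, seq[:200_000]).value
        sigma3 = 3 * np.sqrt(exact * (1 - exact) / 200_000) + 3 / 200_000
        assert abs(emp - exact) < sigma3 + 1e-3


def test_forward_local_densities_agree_for_forward_schemes():
    # both context lengths count the same new-position events
    for sch in small_schemes(2, 2, 2):
        fwd = density.exact_density(sch, mode="forward").exact_fraction
        loc = density.exact_density(sch, mode="local").exact_fraction
        assert fwd == loc


def test_is_forward_detects_violation_with_witness():
    # rule("000") = 2 but both successors pick 0, so e.g. context "0001"
    # jumps backwards: f("000") = 2 > f("001") + 1 = 1
    tab = np.zeros(8, dtype=np.int64)
    tab[0] = 2
    sch = schemes.table_scheme(3, 1, 2, tab)
    ok, witness = density.is_forward(sch)
    assert not ok
    assert witness is not None
    # the witness really violates forwardness
    assert sch.rule(witness[:-1]) > sch.rule(witness[1:]) + 1


def test_verify_uhs_trivial_cases():
    all_members = np.arange(16, dtype=np.int64)
    assert density.verify_uhs(all_members, 2, sigma=2, ell=4)
    assert not density.verify_uhs(np.empty(0, dtype=np.int64), 2, sigma=2, ell=4)
    # a genuinely non-covering set: only the all-zeros 4-mer
    assert not density.verify_uhs(np.array([0]), 2, sigma=2, ell=4)


@pytest.mark.parametrize("w,k,sigma", [(2, 2, 2), (3, 2, 2)])
def test_charged_contexts_are_uhs(w, k, sigma):
    """Forward charged contexts are a (w, l)-UHS and local charged
    contexts a (w, l_local)-UHS, for every built-in scheme."""
    for sch in small_schemes(w, k, sigma):
        fwd = density.charged_contexts_forward(sch)
        assert density.verify_uhs(fwd, w)
        loc = density.charged_contexts_local(sch)
        assert density.verify_uhs(loc, w)


@pytest.mark.parametrize("w,k,sigma", [(2, 2, 2), (3, 2, 2), (2, 3, 2), (4, 2, 2)])
def test_densities_respect_lower_bounds(w, k, sigma):
    for sch in small_schemes(w, k, sigma):
        d = density.exact_density(sch).exact_fraction
        gp = bounds.lower_bound_g_prime(sigma, w, sch.effective_k).value_exact
        assert d >= gp
        # and the charged-context count respects the UHS counting bound
        cs = density.charged_contexts_forward(sch)
        assert len(cs) >= bounds.uhs_lower_bound(sigma, w, cs.context_length)


def test_enumeration_budget_guard():
    sch = schemes.random_minimizer(10, 10, 4, seed=0)
    with pytest.raises(ValueError, match="budget"):
        density.charged_contexts_forward(sch)


def test_empirical_density_requires_one_window():
    sch = schemes.random_minimizer(4, 4, 4, seed=0)
    with pytest.raises(ValueError, match="shorter"):
        density.empirical_density(sch, io.random_sequence(4, 5, 1))
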