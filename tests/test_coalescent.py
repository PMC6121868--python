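"""Simulator checks against closed-form and numeric-integration oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import founderrate as fr
from founderrate import build_schedule
from founderrate.coalescent import SimulationError


def pair_coalescence_prob(N, a, T, g):
    """P(two contemporaneous lineages coalesce before the founding time)."""
    return 1.0 - math.exp(-((T - a) / g) / N)


def p_k1_two_tips(N, mu, a, T, g, L):
    """Numeric integration of P(K=1) for two contemporaneous tips.

    The coalescence time t (generations before the tips) has density
    exp(-t/N)/N truncated at (T-a)/g with an atom there (the forced founder
    merge).  Given t, both pendant branches are t*g years and K=1 iff
    neither carries a mutation: exp(-2 mu L g t).
    """
    Tg = (T - a) / g
    val, _ = quad(lambda t: math.exp(-t / N) / N * math.exp(-2 * mu * L * g * t), 0, Tg)
    return val + math.exp(-Tg / N) * math.exp(-2 * mu * L * (T - a))


def star_k_pmf(ages, mu, L, T, n_max):
    """Poisson-binomial pmf of K in the N -> infinity star limit.

    Each tip's pendant branch (T - age years) mutates independently; with m
    mutated tips, K = m + 1 while some tip is unmutated, else K = n.
    """
    p = [1.0 - math.exp(-mu * L * (T - a)) for a in ages]
    dp = np.zeros(len(p) + 1)
    dp[0] = 1.0
    for pi in p:
        dp[1:] = dp[1:] * (1 - pi) + dp[:-1] * pi
        dp[0] *= 1 - pi
    pmf = np.zeros(n_max + 1)
    for m, w in enumerate(dp):
        k = m + 1 if m < len(p) else len(p)
        pmf[k] += w
    return pmf


def test_single_tip_genealogy_is_one_edge_to_the_founder():
    sched = build_schedule([4000])
    pop = fr.PopulationModel(n_females=100, t_iso_calBP=12_000)
    gen = fr.simulate_genealogy(sched, pop, np.random.default_rng(0))
    assert gen.n_nodes == 2  # the tip and the founder node
    assert gen.time[gen.root] == 12_000
    assert gen.total_branch_length_years == 8000.0


def test_huge_population_yields_star_genealogies(wrangel):
    pop = fr.PopulationModel(n_females=1e12, t_iso_calBP=12_000)
    rng = np.random.default_rng(7)
    n_coalesced = 0
    reps = 10_000
    for _ in range(reps):
        gen = fr.simulate_genealogy(wrangel, pop, rng)
        if gen.n_nodes != 15:  # any pre-founding coalescence adds extra nodes
            n_coalesced += 1
    assert n_coalesced / reps < 0.001


def test_pair_coalescence_probability_matches_closed_form():
    a, T, g, N = 1000.0, 12_000.0, 15.0, 300.0
    sched = build_schedule([a, a])
    pop = fr.PopulationModel(n_females=N, t_iso_calBP=T)
    rng = np.random.default_rng(123)
    reps = 20_000
    hits = 0
    for _ in range(reps):
        gen = fr.simulate_genealogy(sched, pop, rng)
        # a binary coalescence below the founding time adds a fourth node
        hits += int(gen.n_nodes == 4)
    p_hat = hits / reps
    p = pair_coalescence_prob(N, a, T, g)
    se = math.sqrt(p * (1 - p) / reps)
    assert abs(p_hat - p) < 3 * se


def test_genealogy_invariants(wrangel):
    pop = fr.PopulationModel(n_females=164, t_iso_calBP=12_000)
    rng = np.random.default_rng(5)
    for _ in range(50):
        gen = fr.simulate_genealogy(wrangel, pop, rng)
        lens = gen.branch_lengths_years()
        assert (lens[np.arange(gen.n_nodes) != gen.root] > 0).all()
        assert gen.time[gen.root] <= pop.t_iso_calBP
        assert gen.total_branch_length_years > 0


def test_zero_rate_gives_identical_tips_and_k_one(wrangel):
    pop = fr.PopulationModel(n_females=50, t_iso_calBP=12_000)
    mut = fr.MutationModel(mu_per_site_year=0.0, sites_mode="finite")
    rng = np.random.default_rng(11)
    gen = fr.simulate_genealogy(wrangel, pop, rng)
    tips = fr.drop_mutations(gen, mut, rng)
    assert fr.count_haplotypes(tips) == 1
    assert len(set(tips.sequences().values())) == 1
    dist = fr.simulate_k(wrangel, pop, mut, 1000, seed=3)
    assert dist.p(1) == 1.0


def test_poisson_mean_on_star_genealogy(wrangel):
    """Total mutation count on a (near-)star genealogy matches mu*L*B."""
    mu, L = 3e-8, 16_506
    pop = fr.PopulationModel(n_females=1e12, t_iso_calBP=12_000)
    mut = fr.MutationModel(mu_per_site_year=mu, L=L, sites_mode="infinite")
    B = sum(12_000 - a for a in wrangel.ages)
    lam = mu * L * B
    rng = np.random.default_rng(21)
    reps = 10_000
    total = 0
    for _ in range(reps):
        gen = fr.simulate_genealogy(wrangel, pop, rng)
        tips = fr.drop_mutations(gen, mut, rng)
        total += sum(len(s) for s in tips.signatures.values())
    mean = total / reps
    se = math.sqrt(lam / reps)  # Poisson variance = lam
    assert abs(mean - lam) < 3 * se


def test_kappa_one_mutations_are_pure_transitions():
    """With kappa=1 an all-A founder can only ever show G at mutated sites."""
    sched = build_schedule([0])
    pop = fr.PopulationModel(n_females=10, t_iso_calBP=100_000)
    mut = fr.MutationModel(mu_per_site_year=5e-7, L=200, transition_prob=1.0,
                           sites_mode="finite")
    rng = np.random.default_rng(2)
    states = set()
    for _ in range(200):
        gen = fr.simulate_genealogy(sched, pop, rng)
        tips = fr.drop_mutations(gen, mut, rng)
        for sig in tips.signatures.values():
            states.update(st for _, st in sig)
    assert states == {2}  # G


def test_count_haplotypes_examples():
    t = fr.TipStates(mode="infinite", L=10, signatures={
        "a": frozenset(), "b": frozenset(), "c": frozenset()})
    assert fr.count_haplotypes(t) == 1
    t = fr.TipStates(mode="infinite", L=10, signatures={
        "a": frozenset({1}), "b": frozenset({2}), "c": frozenset()})
    assert fr.count_haplotypes(t) == 3


def test_simulate_k_bounds_and_errors(wrangel):
    pop = fr.PopulationModel(n_females=164)
    mut = fr.MutationModel(mu_per_site_year=3e-8)
    dist = fr.simulate_k(wrangel, pop, mut, 500, seed=9)
    assert all(1 <= k <= 14 for k in dist.counts)
    assert math.isclose(sum(dist.frequencies.values()), 1.0)
    assert dist.p(15) == 0.0
    with pytest.raises(SimulationError):
        fr.simulate_k(wrangel, pop, mut, 0, seed=1)
    with pytest.raises(SimulationError):
        fr.simulate_k(wrangel, pop, mut, 10, seed=None)
    with pytest.raises(SimulationError):
        fr.simulate_genealogy(wrangel, pop, None)


def test_simulate_k_deterministic_under_seed(wrangel):
    pop = fr.PopulationModel(n_females=164)
    mut = fr.MutationModel(mu_per_site_year=3e-8, sites_mode="finite")
    d1 = fr.simulate_k(wrangel, pop, mut, 200, seed=77)
    d2 = fr.simulate_k(wrangel, pop, mut, 200, seed=77)
    assert d1.counts == d2.counts
    rng1, rng2 = np.random.default_rng(42), np.random.default_rng(42)
    g1 = fr.simulate_genealogy(wrangel, pop, rng1)
    g2 = fr.simulate_genealogy(wrangel, pop, rng2)
    t1 = fr.drop_mutations(g1, mut, rng1)
    t2 = fr.drop_mutations(g2, mut, rng2)
    assert t1.signatures == t2.signatures


def test_two_tip_k1_matches_numeric_integration(wrangel):
    a, T, g, L = 2000.0, 12_000.0, 15.0, 16_506
    sched = build_schedule([a, a])
    reps = 8000
    for N, mu in [(100, 1e-8), (400, 3e-8)]:
        pop = fr.PopulationModel(n_females=N, t_iso_calBP=T)
        mut = fr.MutationModel(mu_per_site_year=mu, L=L)
        dist = fr.simulate_k(sched, pop, mut, reps, seed=int(N))
        p = p_k1_two_tips(N, mu, a, T, g, L)
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(dist.p(1) - p) < 3 * se + 1e-12


def test_star_limit_k_distribution_matches_poisson_binomial(wrangel):
    mu, L, T = 3e-8, 16_506, 12_000.0
    pop = fr.PopulationModel(n_females=1e10, t_iso_calBP=T)
    mut = fr.MutationModel(mu_per_site_year=mu, L=L)
    reps = 6000
    dist = fr.simulate_k(wrangel, pop, mut, reps, seed=31)
    pmf = star_k_pmf(wrangel.ages, mu, L, T, 14)
    for k in (5, 6, 7, 8):
        se = math.sqrt(pmf[k] * (1 - pmf[k]) / reps)
        assert abs(dist.p(k) - pmf[k]) < 3 * se + 1e-12


def test_mean_k_increases_with_mutation_rate(wrangel):
    pop = fr.PopulationModel(n_females=164)
    reps = 10_000
    mu1 = 3e-10
    means = []
    for mu in (mu1, 100 * mu1):
        mut = fr.MutationModel(mu_per_site_year=mu)
        means.append(fr.simulate_k(wrangel, pop, mut, reps, seed=13).mean)
    assert means[1] > means[0]


def test_finite_and_infinite_sites_agree_at_study_rate(wrangel):
    """Repeat hits are rare at 3e-8 over 16.5 kb, so the two mutation
    representations give the same K distribution within Monte-Carlo error."""
    pop = fr.PopulationModel(n_females=164)
    reps = 3000
    p = {}
    se = {}
    for mode in ("finite", "infinite"):
        mut = fr.MutationModel(mu_per_site_year=3e-8, sites_mode=mode)
        d = fr.simulate_k(wrangel, pop, mut, reps, seed=55)
        p[mode], se[mode] = d.p(7), d.se(7)
    combined = math.sqrt(se["finite"] ** 2 + se["infinite"] ** 2)
    assert abs(p["finite"] - p["infinite"]) < 3 * combined
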