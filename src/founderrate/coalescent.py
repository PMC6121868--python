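"""Heterochronous coalescent with forced founder coalescence.

The model: a single isolated population of constant size ``n_females``
maternal lineages, founded at ``t_iso_calBP``.  Samples enter the genealogy
at their (serial) ages; while ``k`` lineages are active the waiting time to
the next coalescence is exponential with rate ``k (k-1) / 2 * 1/n_females``
per generation, clipped at the next tip-activation time.  Any lineages still
distinct at the isolation time merge simultaneously into the founder node,
so the founding population carries a single haplotype.  Mutations are then
dropped on the genealogy as a Poisson process (``mu * L`` per branch-year)
and the number of distinct haplotypes among the tips, K, is the summary
statistic of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BASES, TRANSITION, TRANSVERSIONS, MutationModel, PopulationModel
from .schedule import SampleSchedule


class SimulationError(ValueError):
    """Invalid simulation inputs (e.g. tips older than the founding time)."""


@dataclass(frozen=True)
class Genealogy:
    """A realized genealogy of serially sampled lineages.

    Nodes ``0..n_tips-1`` are tips (in schedule order, youngest first);
    internal nodes follow in order of creation (increasing age).  Node times
    are in years calBP (larger = older).  The root is always the founder
    node at exactly ``t_iso_calBP``: a simultaneous multi-merger when two or
    more lineages survive to the founding time, otherwise the truncation
    point of the single surviving lineage.  Mutations on the stem between
    the samples' most recent common ancestor and the founder are shared by
    every tip and so never affect the haplotype count.
    """

    tip_ids: tuple[str, ...]
    parent: np.ndarray  # parent[i] = parent node index, -1 for the root
    time: np.ndarray  # node times, years calBP
    t_iso_calBP: float

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def branch_lengths_years(self) -> np.ndarray:
        """Length in years of the branch above each non-root node (0 for root)."""
        lens = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lens[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lens

    @property
    def total_branch_length_years(self) -> float:
        return float(self.branch_lengths_years().sum())


def _simulate_topology(ages_sorted, n_females, t_iso, gen_time, rng):
    """Event-loop core; returns (parent, node_time) as Python lists.

    ``ages_sorted`` are tip ages in years calBP, ascending.  Times are kept
    in years; the coalescence rate per year for k lineages is
    k(k-1)/2 * 1/(n_females * gen_time).
    """
    n = len(ages_sorted)
    max_nodes = 2 * n  # n tips, <= n-1 binary mergers, <= 1 founder node
    parent = [-1] * max_nodes
    node_time = [0.0] * max_nodes
    for i in range(n):
        node_time[i] = ages_sorted[i]
    n_gen_years = n_females * gen_time
    active = [0]
    t = ages_sorted[0]
    j = 1
    nxt = n
    while True:
        k = len(active)
        if k >= 2:
            t_next = t + rng.exponential(2.0 * n_gen_years / (k * (k - 1)))
        else:
            t_next = np.inf
        if j < n and ages_sorted[j] <= min(t_next, t_iso):
            t = ages_sorted[j]
            active.append(j)
            j += 1
            continue
        if t_next < t_iso:
            t = t_next
            i1 = int(rng.integers(k))
            i2 = int(rng.integers(k - 1))
            if i2 >= i1:
                i2 += 1
            if i2 < i1:
                i1, i2 = i2, i1
            c2 = active.pop(i2)
            c1 = active.pop(i1)
            node = nxt
            nxt += 1
            parent[c1] = node
            parent[c2] = node
            node_time[node] = t
            active.append(node)
        else:
            # founder node at exactly t_iso: a simultaneous multi-merger when
            # >= 2 lineages survive, otherwise the single surviving lineage's
            # truncation point (so every genealogy is rooted at the founder)
            node = nxt
            nxt += 1
            for ch in active:
                parent[ch] = node
            node_time[node] = t_iso
            break
    return parent[:nxt], node_time[:nxt]


def simulate_genealogy(
    schedule: SampleSchedule, pop: PopulationModel, rng: np.random.Generator
) -> Genealogy:
    """Simulate one serial-coalescent genealogy with forced founder collapse."""
    if rng is None:
        raise SimulationError("an explicit seeded random generator is required")
    if len(schedule) == 0:
        raise SimulationError("schedule is empty")
    if schedule.max_age >= pop.t_iso_calBP:
        raise SimulationError(
            f"all sample ages must be younger than the isolation time "
            f"({schedule.max_age} >= {pop.t_iso_calBP})"
        )
    ages = schedule.ages
    parent, node_time = _simulate_topology(
        ages, pop.n_females, pop.t_iso_calBP, schedule.generation_time_years, rng
    )
    return Genealogy(
        tip_ids=tuple(schedule.sample_ids),
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(node_time, dtype=float),
        t_iso_calBP=pop.t_iso_calBP,
    )


@dataclass(frozen=True)
class TipStates:
    """Realized tip haplotypes relative to the founder sequence.

    In finite mode each tip's ``signature`` is the frozen set of
    ``(site, state_code)`` pairs where it differs from the founder; the full
    sequence can be materialized with :meth:`sequences`.  In infinite mode a
    signature is the frozen set of mutation identifiers carried by the tip.
    Two tips are the same haplotype iff their signatures are equal.
    """

    mode: str
    L: int
    signatures: dict[str, frozenset]
    founder_base: str = "A"

    def sequences(self) -> dict[str, str]:
        """Materialize full-length tip sequences (finite mode only)."""
        if self.mode != "finite":
            raise ValueError("sequences are only defined in finite-sites mode")
        founder = np.full(self.L, BASES.index(self.founder_base), dtype=np.int8)
        out = {}
        for sid, sig in self.signatures.items():
            seq = founder.copy()
            for site, state in sig:
                seq[site] = state
            out[sid] = "".join(BASES[b] for b in seq)
        return out


def drop_mutations(
    gen: Genealogy, mut: MutationModel, rng: np.random.Generator
) -> TipStates:
    """Drop Poisson mutations on a genealogy and propagate states to the tips.

    Per branch the mutation count is Poisson(mu * L * branch_length_years).
    Finite mode: each mutation hits a uniformly random site; the new state is
    the transition of the current state with probability kappa, otherwise one
    of the two transversions with equal probability.  Infinite mode: every
    mutation is a fresh, private site.  Mutations exist only below the
    founder node (the genealogy is truncated at the isolation time).
    """
    if rng is None:
        raise SimulationError("an explicit seeded random generator is required")
    lens = gen.branch_lengths_years()
    counts = rng.poisson(mut.rate_per_branch_year * lens)
    n_nodes = gen.n_nodes
    founder_code = BASES.index("A")

    # children lists for a root-to-tip traversal
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for i in range(n_nodes):
        p = int(gen.parent[i])
        if p >= 0:
            children[p].append(i)

    if mut.sites_mode == "infinite":
        next_id = 0
        node_sets: dict[int, frozenset] = {gen.root: frozenset()}
        stack = [gen.root]
        while stack:
            node = stack.pop()
            base = node_sets[node]
            for ch in children[node]:
                c = int(counts[ch])
                if c:
                    new = frozenset(range(next_id, next_id + c))
                    next_id += c
                    node_sets[ch] = base | new
                else:
                    node_sets[ch] = base
                stack.append(ch)
        sigs = {gen.tip_ids[i]: node_sets[i] for i in range(gen.n_tips)}
        return TipStates(mode="infinite", L=mut.L, signatures=sigs)

    # finite sites: carry {site: state} overrides relative to the founder
    kappa = mut.transition_prob
    node_over: dict[int, dict[int, int]] = {gen.root: {}}
    stack = [gen.root]
    while stack:
        node = stack.pop()
        base = node_over[node]
        for ch in children[node]:
            c = int(counts[ch])
            if c:
                over = dict(base)
                sites = rng.integers(mut.L, size=c)
                r_trans = rng.random(c)
                r_side = rng.integers(2, size=c)
                for site, rt, side in zip(sites, r_trans, r_side):
                    site = int(site)
                    cur = over.get(site, founder_code)
                    if rt < kappa:
                        new = TRANSITION[cur]
                    else:
                        new = TRANSVERSIONS[cur][side]
                    if new == founder_code:
                        over.pop(site, None)
                    else:
                        over[site] = new
                node_over[ch] = over
            else:
                node_over[ch] = base
            stack.append(ch)
    sigs = {
        gen.tip_ids[i]: frozenset(node_over[i].items()) for i in range(gen.n_tips)
    }
    return TipStates(mode="finite", L=mut.L, signatures=sigs)


def count_haplotypes(tips: TipStates) -> int:
    """Number of distinct haplotypes among the tips (1 <= K <= n)."""
    if not tips.signatures:
        raise ValueError("no tips")
    return len(set(tips.signatures.values()))


@dataclass(frozen=True)
class KDistribution:
    """Empirical Monte-Carlo distribution of the haplotype count K."""

    counts: dict[int, int]
    reps: int

    @property
    def frequencies(self) -> dict[int, float]:
        return {k: c / self.reps for k, c in sorted(self.counts.items())}

    def p(self, k: int) -> float:
        """Estimated P(K = k)."""
        return self.counts.get(k, 0) / self.reps

    def se(self, k: int) -> float:
        """Binomial standard error of the P(K = k) estimate."""
        p = self.p(k)
        return float(np.sqrt(p * (1.0 - p) / self.reps))

    @property
    def mean(self) -> float:
        return sum(k * c for k, c in self.counts.items()) / self.reps


def _count_k_infinite(parent, lens, n_tips, rate, rng) -> int:
    """Haplotype count without materializing mutations (infinite sites).

    Two tips are identical iff no edge on the path between them carries a
    mutation, so contracting mutation-free edges and counting the tip
    classes gives K directly.
    """
    m = len(parent)
    unmut = rng.random(m) < np.exp(-rate * lens)
    uf = list(range(m))

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for ch in range(m):
        if parent[ch] >= 0 and unmut[ch]:
            uf[find(ch)] = find(parent[ch])
    return len({find(i) for i in range(n_tips)})


def simulate_k(
    schedule: SampleSchedule,
    pop: PopulationModel,
    mut: MutationModel,
    reps: int,
    seed,
) -> KDistribution:
    """Monte-Carlo distribution of the haplotype count K over ``reps`` replicates.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; results are
    reproducible and independent of any global random state.
    """
    if reps < 1:
        raise SimulationError("reps must be >= 1")
    if len(schedule) == 0:
        raise SimulationError("schedule is empty")
    if schedule.max_age >= pop.t_iso_calBP:
        raise SimulationError("all sample ages must be younger than the isolation time")
    if seed is None:
        raise SimulationError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    ages = schedule.ages
    n = len(ages)
    g = schedule.generation_time_years
    counts: dict[int, int] = {}
    if mut.sites_mode == "infinite":
        rate = mut.rate_per_branch_year
        for _ in range(reps):
            parent, node_time = _simulate_topology(
                ages, pop.n_females, pop.t_iso_calBP, g, rng
            )
            m = len(parent)
            lens = np.empty(m)
            for i in range(m):
                p = parent[i]
                lens[i] = (node_time[p] - node_time[i]) if p >= 0 else 0.0
            k = _count_k_infinite(parent, lens, n, rate, rng)
            counts[k] = counts.get(k, 0) + 1
    else:
        for _ in range(reps):
            gen = simulate_genealogy(schedule, pop, rng)
            tips = drop_mutations(gen, mut, rng)
            k = count_haplotypes(tips)
            counts[k] = counts.get(k, 0) + 1
    return KDistribution(counts=counts, reps=reps)
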