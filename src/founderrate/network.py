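"""Median-joining haplotype networks and star-pattern diagnostics.

The construction follows the classical median-joining idea: start from the
minimum-spanning network (the union of all minimum spanning trees) over the
observed haplotypes, repeatedly add quasi-median (consensus-of-triplet)
vectors that shorten connections, and finally prune median nodes that no
longer contribute.  With epsilon = 0 (the default, and the only value used
here) candidate medians are accepted only when their connection cost equals
the round's minimum.  Distances are Hamming distances over unmasked columns
where both sequences are determined; ties are broken lexicographically so
the result is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeSet


class NetworkError(ValueError):
    pass

# any symbol other than 'N' (undetermined) or '-' (masked/gap) is a state;
# the algorithm is alphabet-agnostic so tests can use compact binary vectors
_UNDETERMINED = frozenset("N-")


def hamming(a: str, b: str) -> int:
    """Mutational steps between two sequences over mutually determined sites."""
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in _UNDETERMINED and y not in _UNDETERMINED
    )


def minimum_spanning_network(seqs: dict[str, str]) -> nx.Graph:
    """Union of all minimum spanning trees over the given sequences.

    Edges are added level by level in increasing distance; an edge at level
    d is kept iff its endpoints are in different connected components when
    only edges of smaller distance are considered.
    """
    G = nx.Graph()
    for name in seqs:
        G.add_node(name)
    names = sorted(seqs)
    pairs = sorted(
        ((hamming(seqs[a], seqs[b]), a, b) for a, b in combinations(names, 2))
    )
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    i = 0
    while i < len(pairs):
        d = pairs[i][0]
        level = []
        while i < len(pairs) and pairs[i][0] == d:
            level.append(pairs[i])
            i += 1
        keep = [(a, b, d) for d, a, b in level if find(a) != find(b)]
        for a, b, d_ in keep:
            G.add_edge(a, b, weight=d_)
        for a, b, _ in keep:
            parent[find(a)] = find(b)
        if all(find(n) == find(names[0]) for n in names):
            break
    return G


def _quasi_medians(u: str, v: str, w: str, max_candidates: int = 81):
    """Positionwise consensus of a triplet.

    Where two sequences agree the majority state is taken; where all three
    differ each of the three states generates an alternative (the
    quasi-median set).  Undetermined symbols defer to the determined
    majority.  Returns a list of candidate sequences (possibly empty when
    the all-different positions would explode combinatorially).
    """
    options = []
    n_free = 0
    for a, b, c in zip(u, v, w):
        det = [x for x in (a, b, c) if x not in _UNDETERMINED]
        if not det:
            options.append(("N",))
            continue
        distinct = sorted(set(det))
        if len(distinct) == 1:
            options.append((distinct[0],))
        elif len(det) == 3 and len(distinct) == 2:
            # a clear 2:1 majority
            options.append((max(distinct, key=det.count),))
        elif len(distinct) == 2:
            # only two determined states, one vote each: lexicographic tie-break
            options.append((distinct[0],))
        else:
            options.append(tuple(distinct))
            n_free += 1
    if 3 ** n_free > max_candidates:
        return []
    return ["".join(p) for p in product(*options)]


def median_joining_network(haps: HaplotypeSet, epsilon: int = 0) -> nx.Graph:
    """Median-joining network over the haplotypes of a :class:`HaplotypeSet`.

    Nodes carry ``sequence``, ``is_median`` and ``size`` (number of samples,
    0 for inferred medians); edge ``weight`` is the mutational-step
    distance.  Only ``epsilon = 0`` is implemented (candidate medians must
    match the round's minimal connection cost exactly; a positive epsilon
    would also admit costlier ones).
    """
    if epsilon != 0:
        raise NetworkError("only epsilon = 0 is implemented")
    if not haps.representatives:
        raise NetworkError("no haplotypes")
    counts = haps.counts()
    seqs: dict[str, str] = dict(haps.representatives)
    observed = set(seqs)

    median_counter = 0
    seen_seqs = {seq: name for name, seq in seqs.items()}
    for _round in range(64):  # convergence guard; tiny networks converge fast
        G = minimum_spanning_network(seqs)
        candidates: dict[str, int] = {}
        for v in sorted(G.nodes):
            nbrs = sorted(G.neighbors(v))
            for u, w in combinations(nbrs, 2):
                for m in _quasi_medians(seqs[u], seqs[v], seqs[w]):
                    if m in seen_seqs:
                        continue
                    cost = (
                        hamming(m, seqs[u]) + hamming(m, seqs[v]) + hamming(m, seqs[w])
                    )
                    # a useful median strictly shortens the triplet connection
                    direct = (
                        G[u][v]["weight"] + G[v][w]["weight"]
                        if G.has_edge(u, v) and G.has_edge(v, w)
                        else None
                    )
                    if direct is not None and cost >= direct:
                        continue
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        cmin = min(candidates.values())
        for m in sorted(s for s, c in candidates.items() if c == cmin):
            median_counter += 1
            name = f"mv{median_counter}"
            seqs[name] = m
            seen_seqs[m] = name
    else:  # pragma: no cover - convergence guard
        raise NetworkError("median-joining did not converge")

    # prune medians that no longer support the network (degree <= 2 in the
    # spanning network of the remaining sequences)
    while True:
        G = minimum_spanning_network(seqs)
        removable = sorted(
            n for n in G.nodes if n not in observed and G.degree(n) <= 2
        )
        if not removable:
            break
        del seqs[removable[0]]

    G = minimum_spanning_network(seqs)
    net = nx.Graph()
    for name in sorted(seqs):
        net.add_node(
            name,
            sequence=seqs[name],
            is_median=name not in observed,
            size=counts.get(name, 0),
        )
    for a, b, data in G.edges(data=True):
        net.add_edge(a, b, weight=int(data["weight"]))
    return net


@dataclass(frozen=True)
class StarStatistics:
    max_steps_from_modal: int
    mean_steps: float
    n_medians: int


def star_statistics(net: nx.Graph, modal_label: str) -> StarStatistics:
    """Mutational-step distances from the modal haplotype.

    Distances are shortest paths weighted by edge mutational steps, taken to
    every observed (non-median) haplotype.  A star-like cluster shows a
    small maximum (one or two steps in the study system).
    """
    if modal_label not in net:
        raise NetworkError(f"modal label {modal_label!r} not in the network")
    if not nx.is_connected(net):
        raise NetworkError("network is disconnected")
    dist = nx.single_source_dijkstra_path_length(net, modal_label, weight="weight")
    obs = [n for n, d in net.nodes(data=True) if not d.get("is_median", False)
           and n != modal_label]
    steps = [dist[n] for n in obs]
    n_medians = sum(1 for _, d in net.nodes(data=True) if d.get("is_median", False))
    if not steps:
        return StarStatistics(0, 0.0, n_medians)
    return StarStatistics(int(max(steps)), float(np.mean(steps)), n_medians)
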