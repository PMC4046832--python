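"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base loops, exhaustive subset
or orientation enumeration, moralization reachability) and shares no
code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import networkx as nx
import numpy as np


def brute_force_promoter_sum(intervals, window_start, window_end):
    """Per-base summation of bedGraph intervals over [start, end)."""
    total = 0.0
    for start, end, value in intervals:
        for pos in range(int(start), int(end)):
            if window_start <= pos < window_end:
                total += value
    return total


def histogram_mi(a, b):
    """Contingency-table MI in nats, written independently of the package."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    total = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            p_ab = np.mean((a == va) & (b == vb))
            if p_ab == 0:
                continue
            p_a = np.mean(a == va)
            p_b = np.mean(b == vb)
            total += p_ab * np.log(p_ab / (p_a * p_b))
    return total


def empirical_entropy(a):
    a = np.asarray(a)
    ps = [np.mean(a == v) for v in np.unique(a)]
    return -sum(p * np.log(p) for p in ps if p > 0)


def brute_force_maximal_cliques(g: nx.Graph):
    """All maximal cliques of size >= 2 by enumerating every node subset."""
    nodes = list(g.nodes())
    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(g.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.append(set(subset))
    return {frozenset(c) for c in cliques
            if not any(c < other for other in cliques)}


def moralization_d_separated(g: nx.DiGraph, x, y, given):
    """d-separation via the ancestral-moral-graph reachability criterion."""
    given = set(given)
    relevant = {x, y} | given
    ancestral = set(relevant)
    for v in relevant:
        ancestral |= nx.ancestors(g, v)
    sub = g.subgraph(ancestral)
    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes())
    moral.add_edges_from((u, v) for u, v in sub.edges())
    for v in sub.nodes():
        for p1, p2 in combinations(sorted(sub.predecessors(v)), 2):
            moral.add_edge(p1, p2)
    moral.remove_nodes_from(given)
    if x not in moral or y not in moral:
        return True
    return not nx.has_path(moral, x, y)


def enumerate_all_dags(nodes):
    """Every labelled DAG on the given nodes (feasible for <= 4 nodes)."""
    pairs = list(combinations(nodes, 2))
    dags = []
    # each unordered pair is absent, forward, or backward
    for assignment in product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (u, v), state in zip(pairs, assignment):
            if state == 1:
                g.add_edge(u, v)
            elif state == 2:
                g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g):
            dags.append(g)
    return dags


def v_structures(g: nx.DiGraph):
    out = set()
    for v in g.nodes():
        for p1, p2 in combinations(sorted(g.predecessors(v)), 2):
            if not g.has_edge(p1, p2) and not g.has_edge(p2, p1):
                out.add((p1, v, p2))
    return out


def markov_equivalence_class(g: nx.DiGraph):
    """All DAGs with the same skeleton and v-structures as g."""
    skeleton = [tuple(sorted(e)) for e in g.to_undirected().edges()]
    target_v = v_structures(g)
    members = []
    for orientation in product((0, 1), repeat=len(skeleton)):
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes())
        for (u, v), flip in zip(skeleton, orientation):
            h.add_edge(v, u) if flip else h.add_edge(u, v)
        if nx.is_directed_acyclic_graph(h) and v_structures(h) == target_v:
            members.append(h)
    return members


def brute_force_compelled(g: nx.DiGraph):
    """Compelled edges as those oriented identically across the whole
    Markov-equivalence class; everything else in the skeleton is reversible."""
    members = markov_equivalence_class(g)
    compelled = set()
    reversible = set()
    for u, v in g.edges():
        if all(m.has_edge(u, v) for m in members):
            compelled.add((u, v))
        else:
            reversible.add(tuple(sorted((u, v))))
    return compelled, reversible


def random_dag(rng: np.random.Generator, n_nodes: int, p: float = 0.4):
    nodes = [f"n{i}" for i in range(n_nodes)]
    order = list(rng.permutation(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < p:
            g.add_edge(order[i], order[j])
    return g
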