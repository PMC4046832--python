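"""Score-based Bayesian-network structure learning over discretized marks.

The network score is the BDe (Bayesian-Dirichlet equivalent) log marginal
likelihood with a uniform structure prior: for a child with arity r and
parent-configuration count q, every Dirichlet hyperparameter is
ess / (q * r), which makes the score equal across Markov-equivalent DAGs.
The search is greedy hill climbing over single-edge moves (add, delete,
reverse) combined with simulated annealing: a score-decreasing move is
accepted with probability exp(delta / T) under a geometrically cooled
temperature, and the best structure ever visited is returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .io_discretize import DiscreteMatrix

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "bde_family_score", "bde_score", "search_structure"]


@dataclass
class SearchConfig:
    """Hill-climbing / annealing settings.

    max_parents bounds family size for tractability on genome-scale
    matrices; temperature_initial = 0 disables annealing (pure greedy
    acceptance). Scores use equivalent sample size ``ess`` (uniform BDeu).
    """

    max_iterations: int = 10_000
    max_parents: int = 5
    temperature_initial: float = 1.0
    cooling_rate: float = 0.999
    restarts: int = 5
    ess: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not (0.0 < self.cooling_rate < 1.0):
            raise ValidationError("cooling_rate must be in (0, 1)")
        if self.ess <= 0:
            raise ValidationError("ess must be positive")


def _family_counts(d: DiscreteMatrix, child_idx: int,
                   parent_idx: tuple[int, ...]) -> tuple[np.ndarray, int, int]:
    """Contingency counts (q x r) for one family via radix encoding."""
    arities = d.n_categories
    r = int(arities[child_idx])
    q = 1
    code = np.zeros(d.codes.shape[0], dtype=np.int64)
    for p in parent_idx:
        code = code * int(arities[p]) + d.codes[:, p]
        q *= int(arities[p])
    flat = code * r + d.codes[:, child_idx]
    counts = np.bincount(flat, minlength=q * r).reshape(q, r)
    return counts, q, r


def bde_family_score(child: str, parents: set[str] | tuple[str, ...],
                     d: DiscreteMatrix, ess: float = 1.0) -> float:
    """Log BDe marginal likelihood of one family (child | parents), nats."""
    if ess <= 0:
        raise ValidationError("ess must be positive")
    try:
        child_idx = d.mark_names.index(child)
        parent_idx = tuple(sorted(d.mark_names.index(p) for p in parents))
    except ValueError as exc:
        raise ValidationError(f"unknown variable in family {child!r} | {parents}") from exc
    counts, q, r = _family_counts(d, child_idx, parent_idx)
    a_cell = ess / (q * r)
    a_row = ess / q
    row_tot = counts.sum(axis=1)
    score = np.sum(gammaln(a_row) - gammaln(a_row + row_tot))
    score += np.sum(gammaln(a_cell + counts) - gammaln(a_cell))
    return float(score)


def bde_score(g: nx.DiGraph, d: DiscreteMatrix, ess: float = 1.0,
              _cache: dict | None = None) -> float:
    """Decomposable network score: sum of family scores."""
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("BDe score is defined for acyclic graphs only")
    unknown = set(g.nodes()) - set(d.mark_names)
    if unknown:
        raise ValidationError(f"graph nodes not in data: {sorted(unknown)}")
    total = 0.0
    for v in g.nodes():
        key = (v, frozenset(g.predecessors(v)))
        if _cache is not None and key in _cache:
            total += _cache[key]
            continue
        s = bde_family_score(v, set(g.predecessors(v)), d, ess=ess)
        if _cache is not None:
            _cache[key] = s
        total += s
    return total


def _creates_cycle(parents: dict[str, set[str]], src: str, dst: str) -> bool:
    """Would adding src -> dst create a directed cycle? (DFS src reachable from dst)"""
    stack = [src]
    seen = {src}
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        for p in parents[v]:
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return False


def search_structure(d: DiscreteMatrix, cfg: SearchConfig | None = None) -> nx.DiGraph:
    """Greedy hill climbing with simulated annealing over DAGs.

    Moves are single-edge add / delete / reverse, respecting acyclicity
    and ``max_parents``. Each restart begins from the empty graph with a
    fresh temperature; the best-scoring structure ever visited across all
    restarts is returned. Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or SearchConfig()
    nodes = list(d.mark_names)
    if len(nodes) < 2:
        raise ValidationError("need at least 2 variables")
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}

    def fam(child: str, parents: set[str]) -> float:
        key = (child, frozenset(parents))
        if key not in cache:
            cache[key] = bde_family_score(child, parents, d, ess=cfg.ess)
        return cache[key]

    best_edges: set[tuple[str, str]] = set()
    best_score = -math.inf
    n = len(nodes)
    for _ in range(max(1, cfg.restarts)):
        parents: dict[str, set[str]] = {v: set() for v in nodes}
        score = sum(fam(v, parents[v]) for v in nodes)
        if score > best_score:
            best_score = score
            best_edges = set()
        temp = cfg.temperature_initial
        for _ in range(cfg.max_iterations):
            i, j = rng.integers(0, n, size=2)
            while j == i:
                j = rng.integers(0, n)
            u, v = nodes[int(i)], nodes[int(j)]
            delta = 0.0
            apply_move = None
            if u in parents[v]:  # existing edge u -> v: delete or reverse
                if rng.random() < 0.5:
                    delta = fam(v, parents[v] - {u}) - fam(v, parents[v])
                    def apply_move(u=u, v=v):
                        parents[v].discard(u)
                else:  # reverse u -> v to v -> u
                    parents[v].discard(u)
                    ok = (len(parents[u]) < cfg.max_parents
                          and not _creates_cycle(parents, v, u))
                    parents[v].add(u)
                    if not ok:
                        temp *= cfg.cooling_rate
                        continue
                    delta = (fam(v, parents[v] - {u}) - fam(v, parents[v])
                             + fam(u, parents[u] | {v}) - fam(u, parents[u]))
                    def apply_move(u=u, v=v):
                        parents[v].discard(u)
                        parents[u].add(v)
            elif v in parents[u]:
                temp *= cfg.cooling_rate
                continue  # the reverse orientation is proposed via (v, u)
            else:  # add u -> v
                if (len(parents[v]) >= cfg.max_parents
                        or _creates_cycle(parents, u, v)):
                    temp *= cfg.cooling_rate
                    continue
                delta = fam(v, parents[v] | {u}) - fam(v, parents[v])
                def apply_move(u=u, v=v):
                    parents[v].add(u)
            accept = delta > 0 or (
                temp > 0 and rng.random() < math.exp(min(0.0, delta) / temp)
            )
            if accept:
                apply_move()
                score += delta
                if score > best_score:
                    best_score = score
                    best_edges = {(p, c) for c, ps in parents.items() for p in ps}
            temp *= cfg.cooling_rate
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(best_edges)
    return g
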