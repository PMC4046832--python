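"""From learned structure to causal claims: GHC augmentation and compelled edges.

A learned DAG is only identified up to its Markov-equivalence class, so a
single orientation is not causal evidence. An edge is *compelled* when it
has the same orientation in every equivalent DAG (the directed edges of
the CPDAG); those are read as causal relationships between marks. Before
labelling, the discovered general hidden confounders (GHCs) are added as
explicit parent nodes of their clique members and all edges between
marks sharing a GHC are removed - dependence inside a clique is
attributed to the latent regulator, not to direct crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .confounders import GHCSet
from .errors import ValidationError
from .io_discretize import DiscreteMatrix
from .structure_learning import SearchConfig, search_structure

__all__ = [
    "AugmentedNetwork",
    "CompelledSet",
    "d_separated",
    "augment_with_ghcs",
    "compelled_edges",
    "infer_causal_relationships",
]


@dataclass
class AugmentedNetwork:
    """A DAG over marks plus GHC source nodes, after intra-clique pruning."""

    dag: nx.DiGraph
    ghc_nodes: list[str]
    pruned_edges: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CompelledSet:
    """Partition of a DAG's skeleton into compelled and reversible edges.

    ``compelled`` holds directed (source, target) pairs oriented
    identically across the whole Markov-equivalence class; ``reversible``
    holds the remaining skeleton edges as sorted unordered pairs.
    """

    compelled: set[tuple[str, str]] = field(default_factory=set)
    reversible: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        comp_skel = {tuple(sorted(e)) for e in self.compelled}
        if comp_skel & self.reversible:
            raise ValidationError("an edge cannot be both compelled and reversible")


def d_separated(g: nx.DiGraph, x: str, y: str, given: set[str] | None = None) -> bool:
    """Is every path between x and y blocked given the conditioning set?

    Standard serial / diverging / converging rules: a chain or fork is
    blocked by conditioning on its middle node; a collider blocks unless
    it (or a descendant) is conditioned on.
    """
    given = set(given or ())
    for v in {x, y} | given:
        if v not in g:
            raise ValidationError(f"unknown variable {v!r}")
    if x == y:
        raise ValidationError("x and y must differ")
    if x in given or y in given:
        raise ValidationError("x and y must not be in the conditioning set")
    return nx.is_d_separator(g, {x}, {y}, given)


def augment_with_ghcs(g: nx.DiGraph, ghcs: GHCSet) -> AugmentedNetwork:
    """Insert GHC nodes as latent parents and prune intra-clique mark edges.

    Each GHC becomes a new source node with a directed edge to every
    clique member (a regulator causes its marks). Every mark-mark edge
    whose endpoints co-occur in any single GHC is then removed and
    recorded - its dependence is explained by the shared regulator.
    """
    marks = set(g.nodes())
    for ghc_id, members in zip(ghcs.ids, ghcs.ghcs):
        if ghc_id in marks:
            raise ValidationError(f"GHC label {ghc_id!r} collides with a mark name")
        missing = set(members) - marks
        if missing:
            raise ValidationError(f"GHC {ghc_id} members not in graph: {sorted(missing)}")
    aug = g.copy()
    pruned: list[tuple[str, str]] = []
    shared = set()
    for members in ghcs.ghcs:
        mset = set(members)
        for u, v in list(g.edges()):
            if u in mset and v in mset:
                shared.add((u, v))
    for u, v in sorted(shared):
        aug.remove_edge(u, v)
        pruned.append((u, v))
    for ghc_id, members in zip(ghcs.ids, ghcs.ghcs):
        aug.add_node(ghc_id)
        for m in members:
            aug.add_edge(ghc_id, m)
    return AugmentedNetwork(dag=aug, ghc_nodes=list(ghcs.ids), pruned_edges=pruned)


def _order_edges(g: nx.DiGraph) -> list[tuple[str, str]]:
    """Chickering's edge ordering: by topological rank of the head, then
    reverse topological rank of the tail."""
    rank = {v: i for i, v in enumerate(nx.topological_sort(g))}
    unordered = set(g.edges())
    ordered: list[tuple[str, str]] = []
    while unordered:
        y = min({v for _, v in unordered}, key=rank.get)
        x = max((u for u, v in unordered if v == y), key=rank.get)
        ordered.append((x, y))
        unordered.remove((x, y))
    return ordered


def compelled_edges(g: nx.DiGraph) -> CompelledSet:
    """Label every edge of a DAG compelled or reversible (DAG -> CPDAG).

    An edge is compelled when it is oriented the same way in every DAG
    Markov-equivalent to ``g`` (same skeleton and v-structures); the
    labelling follows Chickering's ordered-edge procedure and is
    deterministic.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("compelled edges are defined for acyclic graphs only")
    label: dict[tuple[str, str], str] = {}
    for x, y in _order_edges(g):
        if (x, y) in label:
            continue
        parents_y = set(g.predecessors(y))
        parents_x = set(g.predecessors(x))
        strongly = False
        for w in parents_x:
            if label.get((w, x)) != "compelled":
                continue
            if w not in parents_y:
                for p in parents_y:
                    label[(p, y)] = "compelled"
                strongly = True
                break
            label[(w, y)] = "compelled"
        if strongly:
            continue
        if any(z not in parents_x for z in parents_y if z != x):
            for p in parents_y:
                if label.get((p, y)) != "compelled":
                    label[(p, y)] = "compelled"
        else:
            for p in parents_y:
                if (p, y) not in label:
                    label[(p, y)] = "reversible"
    return CompelledSet(
        compelled={e for e, lab in label.items() if lab == "compelled"},
        reversible={tuple(sorted(e)) for e, lab in label.items()
                    if lab == "reversible"},
    )


def infer_causal_relationships(d: DiscreteMatrix, ghcs: GHCSet,
                               cfg: SearchConfig | None = None,
                               diagnostics: dict | None = None) -> CompelledSet:
    """Full causal step: learn structure, augment with GHCs, extract
    compelled edges, and keep only mark-mark relationships.

    With an empty GHC set this reduces exactly to the no-hidden-variable
    baseline. Pass a dict as ``diagnostics`` to receive the learned DAG,
    the augmented network, and the GHC-incident compelled edges.
    """
    dag = search_structure(d, cfg)
    aug = augment_with_ghcs(dag, ghcs)
    full = compelled_edges(aug.dag)
    marks = set(d.mark_names)
    result = CompelledSet(
        compelled={(u, v) for u, v in full.compelled if u in marks and v in marks},
        reversible={e for e in full.reversible if e[0] in marks and e[1] in marks},
    )
    if diagnostics is not None:
        diagnostics["dag"] = dag
        diagnostics["augmented"] = aug
        diagnostics["ghc_incident_compelled"] = {
            (u, v) for u, v in full.compelled if u not in marks or v not in marks
        }
    return result
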