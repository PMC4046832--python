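"""Hidden-confounder discovery: threshold calibration, PHCs, and GHCs.

A pairwise hidden confounder (PHC) is postulated for two marks whose
mutual information is significant (MI >= beta) but whose dependence is
not mediated by nucleosome positioning (MIG <= alpha). The thresholds
are calibrated by a permutation null: every mark column is shuffled
independently (NucPos stays aligned to genes), MI and MIG are recomputed
for all pairs, and (alpha, beta) are placed so that the selection region
contains no permuted pair. beta sits one ulp above the largest permuted
MI, so no permuted pair is MI-significant; alpha is the upper 0.1%
quantile of the permuted MIG distribution, bounding the MIG magnitude
that pure noise produces, so that a real pair is called confounded only
when its NucPos-mediated information is indistinguishable from zero.

PHCs define the *hidden confounder graph* (marks as nodes, PHCs as
edges); each maximal clique of that graph is one general hidden
confounder (GHC) - a single latent regulator postulated for the whole
clique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .infotheory import KernelConfig, PairDependency, pairwise_dependency_table
from .io_discretize import DiscreteMatrix

__all__ = [
    "Thresholds",
    "GHCSet",
    "calibrate_thresholds",
    "select_phcs",
    "build_confounder_graph",
    "enumerate_maximal_cliques",
]

_MIG_QUANTILES = (0.001, 0.01, 0.5, 0.99, 0.999, 1.0)


@dataclass
class Thresholds:
    """Calibrated (alpha, beta) plus the permutation-null summaries."""

    alpha: float
    beta: float
    n_permutations: int
    permuted_mi_max: float
    permuted_mig_summary: dict[float, float] = field(default_factory=dict)


@dataclass
class GHCSet:
    """Maximal cliques of the hidden-confounder graph (size >= 2).

    Members are stored sorted; cliques are labelled GHC1..GHCk in
    canonical (sorted-members) order.
    """

    ghcs: list[tuple[str, ...]]
    ids: list[str]

    def __post_init__(self) -> None:
        for g in self.ghcs:
            if len(g) < 2:
                raise ValidationError("every GHC must have at least 2 members")
        for a in self.ghcs:
            for b in self.ghcs:
                if a != b and set(a) <= set(b):
                    raise ValidationError(f"GHC {a} is contained in {b}: not maximal")

    def __len__(self) -> int:
        return len(self.ghcs)

    @classmethod
    def empty(cls) -> "GHCSet":
        return cls(ghcs=[], ids=[])


def calibrate_thresholds(d: DiscreteMatrix, nucpos: np.ndarray,
                         cfg: KernelConfig | None = None,
                         n_perm: int = 1000,
                         seed: int | None = None,
                         estimator: str = "plugin",
                         z_bins: int = 5,
                         mig_quantile: float = 0.999) -> Thresholds:
    """Permutation calibration of the PHC selection thresholds.

    Each permutation independently shuffles every mark column while the
    NucPos track stays aligned to genes, so exactly the mark-mark
    dependence is nulled. The returned region {MIG <= alpha, MI >= beta}
    contains no permuted pair.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    if not len(d.mark_names):
        raise ValidationError("empty matrix")
    rng = np.random.default_rng(seed)
    mis: list[float] = []
    migs: list[float] = []
    for _ in range(n_perm):
        permuted = np.column_stack(
            [rng.permutation(d.codes[:, j]) for j in range(d.codes.shape[1])]
        )
        dp = DiscreteMatrix(gene_ids=list(d.gene_ids), mark_names=list(d.mark_names),
                            codes=permuted, K=d.K, bin_edges=d.bin_edges,
                            n_categories=d.n_categories)
        for rec in pairwise_dependency_table(dp, nucpos, cfg=cfg,
                                             estimator=estimator, z_bins=z_bins):
            mis.append(rec.mi)
            migs.append(rec.mig)
    mis_arr = np.asarray(mis)
    migs_arr = np.asarray(migs)
    beta = float(np.nextafter(mis_arr.max(), np.inf))
    alpha = float(np.quantile(migs_arr, mig_quantile))
    # defensive: the region must be empty of permuted pairs
    inside = (migs_arr <= alpha) & (mis_arr >= beta)
    if inside.any():  # pragma: no cover - excluded by construction
        alpha = float(np.nextafter(migs_arr[mis_arr >= beta].min(), -np.inf))
    summary = {q: float(np.quantile(migs_arr, q)) for q in _MIG_QUANTILES}
    return Thresholds(alpha=alpha, beta=beta, n_permutations=n_perm,
                      permuted_mi_max=float(mis_arr.max()),
                      permuted_mig_summary=summary)


def select_phcs(pairs: list[PairDependency], t: Thresholds) -> list[tuple[str, str]]:
    """Pairs with MIG <= alpha and MI >= beta, in input order."""
    return [(p.mark_a, p.mark_b) for p in pairs
            if p.mig <= t.alpha and p.mi >= t.beta]


def build_confounder_graph(phcs: list[tuple[str, str]],
                           marks: list[str]) -> nx.Graph:
    """Undirected graph with every mark as a node and PHCs as edges."""
    known = set(marks)
    g = nx.Graph()
    g.add_nodes_from(marks)
    for a, b in phcs:
        if a not in known or b not in known:
            raise ValidationError(f"PHC ({a}, {b}) names an unknown mark")
        if a == b:
            raise ValidationError(f"self-loop PHC on {a}")
        g.add_edge(a, b)
    return g


def enumerate_maximal_cliques(g: nx.Graph) -> GHCSet:
    """All maximal cliques of size >= 2, labelled GHC1..GHCk.

    Isolated nodes yield no GHC. Cliques are sorted by their sorted
    member tuples for a canonical labelling.
    """
    cliques = sorted(
        tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= 2
    )
    return GHCSet(ghcs=cliques, ids=[f"GHC{i + 1}" for i in range(len(cliques))])
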