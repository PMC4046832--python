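"""Bootstrap confidence for inferred relationships and derived scores.

Genes (rows) are resampled with replacement and the full inference chain
is rerun per replicate with thresholds held fixed at their original
calibration: discretize, pairwise dependence, PHC/GHC derivation,
structure learning, GHC augmentation, compelled-edge extraction. The
confidence of a feature is the fraction of replicates in which it
recurs: compelled edges, ancestor relations C0(X, Y) (via compelled
edges only), and Markov relations (adjacency or a shared child in the
replicate's learned DAG).

The dominance score of a mark, dScore(X) = sum_Y C0(X, Y)^k, rewards
marks that are confident ancestors of many others; k > 1 up-weights the
most significant relations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .causal_inference import augment_with_ghcs, compelled_edges
from .confounders import Thresholds, build_confounder_graph, enumerate_maximal_cliques, select_phcs
from .errors import ValidationError
from .infotheory import KernelConfig, pairwise_dependency_table
from .io_discretize import MarkMatrix, discretize, log_transform_nucpos
from .structure_learning import SearchConfig, search_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "BootstrapSummary",
    "DominanceTable",
    "bootstrap_confidence",
    "dominance_score",
    "threshold_network",
]


@dataclass
class PipelineConfig:
    """Frozen settings for one end-to-end inference run.

    Thresholds (alpha, beta) are calibrated once on the original data and
    are NOT recalibrated inside bootstrap replicates.
    """

    thresholds: Thresholds
    search: SearchConfig = field(default_factory=SearchConfig)
    k_categories: int = 3
    estimator: str = "plugin"
    kernel_cfg: KernelConfig | None = None
    z_bins: int = 5


@dataclass
class BootstrapSummary:
    """Per-feature recurrence frequencies over bootstrap replicates."""

    n_boot: int
    edge_conf: dict[tuple[str, str], float]
    ancestor_conf: dict[tuple[str, str], float]
    markov_conf: dict[tuple[str, str], float]
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, m in (("edge", self.edge_conf), ("ancestor", self.ancestor_conf),
                        ("markov", self.markov_conf)):
            for k, v in m.items():
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{name} confidence for {k} outside [0, 1]")


@dataclass
class DominanceTable:
    """dScore per mark plus the descending ranking."""

    k: float
    scores: dict[str, float]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = sorted(self.scores, key=lambda m: (-self.scores[m], m))


def _run_replicate(m: MarkMatrix, cfg: PipelineConfig, idx: np.ndarray,
                   search_seed: int) -> tuple[set, set, set]:
    """One bootstrap replicate: returns (compelled mark edges, ancestor
    pairs, markov pairs)."""
    counts = m.counts[idx]
    nucpos = m.nucpos[idx]
    rep = MarkMatrix(gene_ids=[f"g{i}" for i in range(len(idx))],
                     mark_names=list(m.mark_names), counts=counts,
                     nucpos=nucpos, nucpos_scale=m.nucpos_scale)
    disc = discretize(rep, K=cfg.k_categories)
    pairs = pairwise_dependency_table(disc, rep.nucpos, cfg=cfg.kernel_cfg,
                                      estimator=cfg.estimator, z_bins=cfg.z_bins)
    phcs = select_phcs(pairs, cfg.thresholds)
    ghcs = enumerate_maximal_cliques(build_confounder_graph(phcs, rep.mark_names))
    search = SearchConfig(**{**cfg.search.__dict__, "seed": search_seed})
    dag = search_structure(disc, search)
    aug = augment_with_ghcs(dag, ghcs)
    comp = compelled_edges(aug.dag)
    marks = set(m.mark_names)
    edges = {(u, v) for u, v in comp.compelled if u in marks and v in marks}
    anc_graph = nx.DiGraph()
    anc_graph.add_nodes_from(marks)
    anc_graph.add_edges_from(edges)
    ancestors = {(x, y) for x in marks for y in nx.descendants(anc_graph, x)}
    markov = set()
    for a, b in combinations(sorted(marks), 2):
        adjacent = dag.has_edge(a, b) or dag.has_edge(b, a)
        shared_child = bool(set(dag.successors(a)) & set(dag.successors(b)))
        if adjacent or shared_child:
            markov.add((a, b))
    return edges, ancestors, markov


def bootstrap_confidence(m: MarkMatrix, pipeline_cfg: PipelineConfig,
                         n_boot: int = 100,
                         seed: int | None = None) -> BootstrapSummary:
    """Rerun the full chain on gene-resampled replicates and tally features.

    A replicate that fails is retried once with a fresh resample, then
    counted as containing no features (with a warning).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if m.nucpos is None:
        raise ValidationError("bootstrap pipeline requires a NucPos track")
    if m.nucpos_scale == "raw":
        m = log_transform_nucpos(m)
    rng = np.random.default_rng(seed)
    n = m.n_genes
    marks = sorted(m.mark_names)
    edge_n = {p: 0 for p in ((a, b) for a in marks for b in marks if a != b)}
    anc_n = {p: 0 for p in edge_n}
    markov_n = {p: 0 for p in combinations(marks, 2)}
    for _ in range(n_boot):
        for attempt in range(2):
            idx = rng.integers(0, n, size=n)
            search_seed = int(rng.integers(0, 2**31 - 1))
            try:
                edges, ancestors, markov = _run_replicate(m, pipeline_cfg, idx,
                                                          search_seed)
                break
            except Exception as exc:  # pragma: no cover - defensive
                if attempt == 1:
                    warnings.warn(f"bootstrap replicate failed twice ({exc}); "
                                  "counted as feature-free", stacklevel=2)
                    edges, ancestors, markov = set(), set(), set()
        for e in edges:
            edge_n[e] += 1
        for p in ancestors:
            anc_n[p] += 1
        for p in markov:
            markov_n[p] += 1
    return BootstrapSummary(
        n_boot=n_boot,
        edge_conf={p: c / n_boot for p, c in edge_n.items()},
        ancestor_conf={p: c / n_boot for p, c in anc_n.items()},
        markov_conf={p: c / n_boot for p, c in markov_n.items()},
        seed=seed,
    )


def dominance_score(b: BootstrapSummary, k: float = 2.0) -> DominanceTable:
    """dScore(X) = sum over Y of C0(X, Y)^k, per mark."""
    if k <= 0:
        raise ValidationError("k must be positive")
    marks = sorted({x for x, _ in b.ancestor_conf} | {y for _, y in b.ancestor_conf})
    scores = {
        x: float(sum(c ** k for (a, _), c in b.ancestor_conf.items() if a == x))
        for x in marks
    }
    return DominanceTable(k=k, scores=scores)


def threshold_network(b: BootstrapSummary,
                      cutoff: float) -> list[tuple[str, str, float]]:
    """Compelled edges with confidence >= cutoff, most confident first."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must be in [0, 1]")
    edges = [(u, v, c) for (u, v), c in b.edge_conf.items()
             if c >= cutoff and c > 0]
    return sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
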