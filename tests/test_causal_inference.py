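from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from chromcause import (CompelledSet, DiscreteMatrix, GHCSet, SearchConfig,
                        augment_with_ghcs, compelled_edges, d_separated,
                        infer_causal_relationships, search_structure)
from chromcause.errors import ValidationError
from oracles import brute_force_compelled, moralization_d_separated, random_dag


class TestDSeparated:
    def test_serial_chain_blocked_by_middle(self):
        g = nx.DiGraph([("x", "z"), ("z", "y")])
        assert d_separated(g, "x", "y", {"z"})
        assert not d_separated(g, "x", "y", set())

    def test_collider_opens_when_conditioned(self):
        g = nx.DiGraph([("x", "z"), ("y", "z")])
        assert d_separated(g, "x", "y", set())
        assert not d_separated(g, "x", "y", {"z"})

    def test_diverging_fork_blocked_by_root(self):
        g = nx.DiGraph([("z", "x"), ("z", "y")])
        assert not d_separated(g, "x", "y", set())
        assert d_separated(g, "x", "y", {"z"})

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_moralization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_dag(rng, 5, p=0.45)
        nodes = sorted(g.nodes())
        for x, y in combinations(nodes, 2):
            rest = [v for v in nodes if v not in (x, y)]
            for mask in range(1 << len(rest)):
                given = {rest[i] for i in range(len(rest)) if mask >> i & 1}
                assert d_separated(g, x, y, given) == \
                    moralization_d_separated(g, x, y, given)

    def test_unknown_variable_rejected(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(ValidationError, match="unknown"):
            d_separated(g, "a", "zzz", set())


class TestAugmentWithGhcs:
    def test_edge_inside_ghc_is_pruned(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        ghcs = GHCSet(ghcs=[("A", "B")], ids=["GHC1"])
        aug = augment_with_ghcs(g, ghcs)
        assert aug.pruned_edges == [("A", "B")]
        assert aug.dag.has_edge("GHC1", "A") and aug.dag.has_edge("GHC1", "B")
        assert not aug.dag.has_edge("A", "B")
        assert aug.dag.has_edge("B", "C")

    def test_ghc_without_internal_edge_prunes_nothing(self):
        g = nx.DiGraph([("A", "B")])
        g.add_nodes_from(["C", "D"])
        aug = augment_with_ghcs(g, GHCSet(ghcs=[("C", "D")], ids=["GHC1"]))
        assert aug.pruned_edges == []
        assert aug.dag.has_edge("GHC1", "C") and aug.dag.has_edge("GHC1", "D")

    @pytest.mark.parametrize("seed", range(4))
    def test_acyclicity_preserved(self, seed):
        rng = np.random.default_rng(seed)
        g = random_dag(rng, 6, p=0.4)
        members = tuple(sorted(g.nodes())[:3])
        aug = augment_with_ghcs(g, GHCSet(ghcs=[members], ids=["GHC1"]))
        assert nx.is_directed_acyclic_graph(aug.dag)
        assert aug.dag.in_degree("GHC1") == 0

    def test_label_collision_rejected(self):
        g = nx.DiGraph()
        g.add_nodes_from(["GHC1", "B"])
        with pytest.raises(ValidationError, match="collides"):
            augment_with_ghcs(g, GHCSet(ghcs=[("GHC1", "B")], ids=["GHC1"]))


class TestCompelledEdges:
    def test_v_structure_fully_compelled(self):
        g = nx.DiGraph([("A", "C"), ("B", "C")])
        out = compelled_edges(g)
        assert out.compelled == {("A", "C"), ("B", "C")}
        assert out.reversible == set()

    def test_chain_fully_reversible(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        out = compelled_edges(g)
        assert out.compelled == set()
        assert out.reversible == {("A", "B"), ("B", "C")}

    def test_edge_out_of_collider_is_compelled(self):
        # A -> C <- B plus C -> D: C -> D must be oriented away from the
        # collider in every equivalent DAG
        g = nx.DiGraph([("A", "C"), ("B", "C"), ("C", "D")])
        out = compelled_edges(g)
        assert ("C", "D") in out.compelled

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_equivalence_class_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_dag(rng, 5, p=0.5)
        ours = compelled_edges(g)
        comp, rev = brute_force_compelled(g)
        assert ours.compelled == comp
        assert ours.reversible == rev

    def test_skeleton_covered_exactly_once(self):
        rng = np.random.default_rng(9)
        g = random_dag(rng, 6, p=0.5)
        out = compelled_edges(g)
        skeleton = {tuple(sorted(e)) for e in g.edges()}
        covered = {tuple(sorted(e)) for e in out.compelled} | out.reversible
        assert covered == skeleton
        assert not ({tuple(sorted(e)) for e in out.compelled} & out.reversible)

    def test_cyclic_input_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValidationError, match="acyclic"):
            compelled_edges(g)


class TestInferCausalRelationships:
    @staticmethod
    def _chain_data(seed, n=1500):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, n)
        y = (x + (rng.random(n) < 0.15)) % 3
        z = (y + (rng.random(n) < 0.15)) % 3
        return DiscreteMatrix(gene_ids=[f"g{i}" for i in range(n)],
                              mark_names=["x", "y", "z"],
                              codes=np.column_stack([x, y, z]), K=3)

    @pytest.mark.parametrize("seed", range(4))
    def test_compelled_edges_stay_in_true_skeleton(self, seed):
        d = self._chain_data(seed)
        cfg = SearchConfig(max_iterations=1500, restarts=2, seed=seed)
        out = infer_causal_relationships(d, GHCSet.empty(), cfg)
        true_skeleton = {("x", "y"), ("y", "z")}
        for u, v in out.compelled:
            assert tuple(sorted((u, v))) in true_skeleton

    def test_empty_ghcs_reduce_to_baseline(self):
        d = self._chain_data(0)
        cfg = SearchConfig(max_iterations=800, restarts=1, seed=5)
        via_pipeline = infer_causal_relationships(d, GHCSet.empty(), cfg)
        dag = search_structure(d, cfg)
        direct = compelled_edges(dag)
        assert via_pipeline.compelled == direct.compelled
        assert via_pipeline.reversible == direct.reversible

    def test_diagnostics_channel_reports_ghc_edges(self):
        d = self._chain_data(1)
        diag: dict = {}
        cfg = SearchConfig(max_iterations=800, restarts=1, seed=6)
        out = infer_causal_relationships(
            d, GHCSet(ghcs=[("x", "y")], ids=["GHC1"]), cfg, diagnostics=diag)
        assert "dag" in diag and "augmented" in diag
        assert all(u != "GHC1" and v != "GHC1" for u, v in out.compelled)
        # the pruned x-y edge cannot reappear as a compelled mark edge
        assert ("x", "y") not in out.compelled
        assert ("y", "x") not in out.compelled
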