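"""HAC and clique-DAG clustering, threshold cuts and their invariants."""

import itertools

import numpy as np
import pytest

from gosimclust.clustering import (clixo_cluster, cut_tree, dag_clusters_at_thresholds,
                                   default_thresholds, hac_cluster, write_cluster_sets,
                                   write_inferred_dag)
from gosimclust.similarity import GeneSimMatrix, MeasureSpec

from .conftest import block_sim_matrix, planted_hierarchy_matrix


def _sim(genes, values):
    return GeneSimMatrix(genes=genes, values=np.array(values, dtype=float),
                         spec=MeasureSpec(term_measure="lin", combiner="MAX"))


class TestHac:
    def test_two_genes_single_merge_normalized(self):
        sim = _sim(["a", "b"], [[1.0, 0.6], [0.6, 1.0]])
        tree = hac_cluster(sim)
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_three_gene_merge_order(self):
        # AB similar (0.9), C distant: first merge {A,B}, then with C
        sim = _sim(["A", "B", "C"], [[1, 0.9, 0.1], [0.9, 1, 0.1], [0.1, 0.1, 1]])
        tree = hac_cluster(sim)
        first = set(tree.linkage_matrix[0, :2].astype(int))
        assert first == {0, 1}
        assert tree.linkage_matrix[1, 2] == pytest.approx(1.0)

    def test_average_linkage_against_hand_oracle(self, two_block_matrix):
        """Two 4-gene blocks: within-distance 0.1, across 0.9; average
        linkage merges each block fully before joining them at 0.9."""
        tree = hac_cluster(two_block_matrix)
        heights = tree.linkage_matrix[:, 2]
        # six within-block merges at 0.1/0.9 normalized, then root at 1
        assert np.allclose(heights[:6], 0.1 / 0.9)
        assert heights[6] == pytest.approx(1.0)
        mid = cut_tree(tree, [0.5])[0]
        assert sorted(map(sorted, mid.clusters)) == [
            [f"b0g{i}" for i in range(4)], [f"b1g{i}" for i in range(4)]]
        assert not mid.singletons

    def test_asymmetric_matrix_rejected(self):
        bad = GeneSimMatrix.__new__(GeneSimMatrix)
        bad.genes = ["a", "b"]
        bad.values = np.array([[1.0, 0.2], [0.4, 1.0]])
        bad.spec = MeasureSpec(term_measure="lin", combiner="MAX")
        with pytest.raises(ValueError):
            hac_cluster(bad)


class TestCutTree:
    def test_threshold_near_zero_all_singletons(self, two_block_matrix):
        tree = hac_cluster(two_block_matrix)
        cs = cut_tree(tree, [1e-9])[0]
        assert not cs.clusters
        assert len(cs.singletons) == 8

    def test_threshold_one_single_cluster(self, two_block_matrix):
        tree = hac_cluster(two_block_matrix)
        cs = cut_tree(tree, [1.0])[0]
        assert len(cs.clusters) == 1
        assert cs.clusters[0] == frozenset(two_block_matrix.genes)

    def test_partition_property_every_threshold(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            n = 12
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            sim = _sim([f"g{i}" for i in range(n)], v)
            sets = cut_tree(hac_cluster(sim), default_thresholds())
            for cs in sets:
                counts = {}
                for c in cs.clusters:
                    for g in c:
                        counts[g] = counts.get(g, 0) + 1
                for g in cs.singletons:
                    counts[g] = counts.get(g, 0) + 1
                assert counts == {f"g{i}": 1 for i in range(n)}

    def test_monotone_coarsening(self):
        rng = np.random.default_rng(31)
        n = 10
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        sim = _sim([f"g{i}" for i in range(n)], v)
        sets = cut_tree(hac_cluster(sim), default_thresholds())
        for fine, coarse in zip(sets, sets[1:]):
            units = list(fine.clusters) + [frozenset([g]) for g in fine.singletons]
            targets = list(coarse.clusters) + [frozenset([g]) for g in coarse.singletons]
            for u in units:
                assert any(u <= t for t in targets)


def brute_force_cliques(genes, values, cutoff):
    """Independent oracle: maximal cliques by subset enumeration (<=20 genes)."""
    idx = {g: i for i, g in enumerate(genes)}
    cliques = []
    for r in range(2, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            if all(values[idx[a], idx[b]] >= cutoff
                   for a, b in itertools.combinations(combo, 2)):
                cliques.append(frozenset(combo))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestClixo:
    def test_uniform_similarity_single_root(self):
        sim = _sim(["a", "b", "c"], [[1, .5, .5], [.5, 1, .5], [.5, .5, 1]])
        dag = clixo_cluster(sim)
        sets = {s for s, _ in dag.terms}
        assert sets == {frozenset(["a", "b", "c"])}

    def test_two_block_terms(self, two_block_matrix):
        dag = clixo_cluster(two_block_matrix)
        sets = {s for s, _ in dag.terms}
        b0 = frozenset(f"b0g{i}" for i in range(4))
        b1 = frozenset(f"b1g{i}" for i in range(4))
        assert sets == {b0, b1, b0 | b1}

    def test_planted_hierarchy_recovered_exactly(self):
        sim, modules = planted_hierarchy_matrix()
        dag = clixo_cluster(sim)
        assert {s for s, _ in dag.terms} == set(modules)
        # cross-check each sweep level against the brute-force clique oracle
        for cutoff in (0.9, 0.5, 0.1):
            oracle = brute_force_cliques(sim.genes, sim.values, cutoff)
            created = {s for s, c in dag.terms if abs(c - cutoff) < 0.025}
            assert oracle == created

    def test_containment_invariant_and_cutoffs(self):
        rng = np.random.default_rng(41)
        n = 10
        v = np.round(rng.random((n, n)), 2)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        sim = _sim([f"g{i}" for i in range(n)], v)
        dag = clixo_cluster(sim)  # __post_init__ asserts containment + cutoffs
        root_sets = [s for s, _ in dag.terms if s == frozenset(sim.genes)]
        assert len(root_sets) == 1

    def test_determinism(self):
        sim, _ = planted_hierarchy_matrix()
        d1 = clixo_cluster(sim)
        d2 = clixo_cluster(sim)
        assert d1.terms == d2.terms and d1.edges == d2.edges

    def test_node_budget(self, two_block_matrix):
        with pytest.raises(ValueError, match="budget"):
            clixo_cluster(two_block_matrix, max_genes=4)

    def test_parameter_validation(self, two_block_matrix):
        with pytest.raises(ValueError):
            clixo_cluster(two_block_matrix, alpha=0)
        with pytest.raises(ValueError):
            clixo_cluster(two_block_matrix, beta=0)


class TestDagThresholds:
    def test_low_threshold_leaf_terms(self):
        sim, modules = planted_hierarchy_matrix()
        dag = clixo_cluster(sim)
        cs = dag_clusters_at_thresholds(dag, [0.15])[0]
        assert set(cs.clusters) == set(modules[:4])

    def test_threshold_one_root(self):
        sim, modules = planted_hierarchy_matrix()
        dag = clixo_cluster(sim)
        cs = dag_clusters_at_thresholds(dag, [1.0])[0]
        assert cs.clusters == [modules[6]]
        assert not cs.singletons

    def test_mid_threshold_mid_modules(self):
        sim, modules = planted_hierarchy_matrix()
        dag = clixo_cluster(sim)
        cs = dag_clusters_at_thresholds(dag, [0.55])[0]
        assert set(cs.clusters) == set(modules[4:6])

    def test_every_gene_covered(self):
        sim, _ = planted_hierarchy_matrix()
        dag = clixo_cluster(sim)
        for cs in dag_clusters_at_thresholds(dag, default_thresholds()):
            assert cs.genes == frozenset(sim.genes)


def test_writers_produce_tsv(tmp_path, two_block_matrix):
    tree = hac_cluster(two_block_matrix)
    sets = cut_tree(tree, default_thresholds())
    p1 = tmp_path / "clusters.tsv"
    write_cluster_sets(sets, str(p1))
    lines = p1.read_text().splitlines()
    assert lines[0] == "threshold\tcluster\tgene"
    assert len(lines) == 1 + 10 * 8  # every gene at every threshold
    dag = clixo_cluster(two_block_matrix)
    p2 = tmp_path / "dag.tsv"
    write_inferred_dag(dag, str(p2))
    assert any("\tgene" in ln for ln in p2.read_text().splitlines())
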