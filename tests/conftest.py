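"""Shared fixtures: the hand-worked 5-gene corpus, block similarity
matrices, the planted 3-level hierarchy, and random-corpus helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gosimclust.annotations import AnnotationSet, compute_ic
from gosimclust.ontology import OntologyDAG, build_dag
from gosimclust.similarity import GeneSimMatrix, MeasureSpec


@pytest.fixture
def five_gene_dag() -> OntologyDAG:
    """Root R; C, D under R; siblings A, B under C."""
    return build_dag([("C", "R", "is_a"), ("D", "R", "is_a"),
                      ("A", "C", "is_a"), ("B", "C", "is_a")])


@pytest.fixture
def five_gene_ann(five_gene_dag) -> AnnotationSet:
    """Worked corpus: 2 genes on A, 2 on B, 1 on D.

    Closure counts give p(A)=p(B)=0.4, p(C)=0.8, p(D)=0.2, p(R)=1, so
    IC(A)=IC(B)=0.9163, IC(C)=0.2231, IC(D)=1.6094 (natural log).
    """
    return AnnotationSet({"g1": {"A"}, "g2": {"A"}, "g3": {"B"},
                          "g4": {"B"}, "g5": {"D"}}, five_gene_dag)


@pytest.fixture
def five_gene_ic(five_gene_ann):
    return compute_ic(five_gene_ann)


def block_sim_matrix(block_sizes: list[int], within: float = 0.9,
                     between: float = 0.1) -> GeneSimMatrix:
    """Genes in equally coherent blocks: `within` inside, `between` across."""
    genes, labels = [], []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            genes.append(f"b{b}g{i}")
            labels.append(b)
    n = len(genes)
    values = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                values[i, j] = within
    np.fill_diagonal(values, 1.0)
    return GeneSimMatrix(genes=genes, values=values,
                         spec=MeasureSpec(term_measure="lin", combiner="MAX"))


@pytest.fixture
def two_block_matrix() -> GeneSimMatrix:
    return block_sim_matrix([4, 4])


def planted_hierarchy_matrix() -> tuple[GeneSimMatrix, list[frozenset[str]]]:
    """12 genes in a 3-level hierarchy: 4 leaf modules of 3 genes (sim 0.9),
    2 mid modules of 6 (sim 0.5), one root of all 12 (sim 0.1).

    Returns the matrix and the 7 planted module gene sets.
    """
    leaves = [[f"{c}{i}" for i in range(3)] for c in "abcd"]
    genes = [g for leaf in leaves for g in leaf]
    idx = {g: k for k, g in enumerate(genes)}
    values = np.full((12, 12), 0.1)
    mids = [leaves[0] + leaves[1], leaves[2] + leaves[3]]
    for mid in mids:
        for g in mid:
            for h in mid:
                values[idx[g], idx[h]] = 0.5
    for leaf in leaves:
        for g in leaf:
            for h in leaf:
                values[idx[g], idx[h]] = 0.9
    np.fill_diagonal(values, 1.0)
    modules = ([frozenset(leaf) for leaf in leaves]
               + [frozenset(mid) for mid in mids] + [frozenset(genes)])
    mat = GeneSimMatrix(genes=genes, values=values,
                        spec=MeasureSpec(term_measure="lin", combiner="MAX"))
    return mat, modules


def random_annotation_set(rng: np.random.Generator, n_genes: int = 10,
                          max_terms: int = 4) -> AnnotationSet:
    """Small random corpus over a fixed 3-level tree, for property tests."""
    edges = [("L1", "R", "is_a"), ("L2", "R", "is_a")]
    terms = []
    for parent in ("L1", "L2"):
        for i in range(3):
            t = f"{parent}.{i}"
            terms.append(t)
            edges.append((t, parent, "is_a"))
            for j in range(2):
                tt = f"{t}.{j}"
                terms.append(tt)
                edges.append((tt, t, "is_a"))
    dag = build_dag(edges)
    pool = terms + ["L1", "L2"]
    ann = {}
    for g in range(n_genes):
        k = int(rng.integers(1, max_terms + 1))
        ann[f"g{g}"] = set(rng.choice(pool, size=k, replace=False).tolist())
    return AnnotationSet(ann, dag)
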