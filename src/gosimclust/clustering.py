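"""Gene clustering from a similarity matrix, two ways.

Hierarchical agglomerative clustering (default average linkage / UPGMA)
on distance 1 - similarity, with merge heights normalized so thresholds
run from the leaves (0) to the root (1); and a CliXO-style
threshold-sweep clique method that infers a DAG of possibly overlapping
gene modules.  Both are reduced to :class:`ClusterSet` collections at 10
equally spaced thresholds for evaluation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .similarity import GeneSimMatrix


def default_thresholds(k: int = 10) -> list[float]:
    """k equally spaced thresholds in (0, 1]: i/k for i = 1..k."""
    return [i / k for i in range(1, k + 1)]


@dataclass
class ClusterSet:
    """Clusters (gene sets of size >= 2) plus singletons at one threshold.

    HAC cluster sets partition the gene universe; DAG cluster sets may
    contain overlapping clusters.  Every gene appears in at least one
    cluster or as a singleton.
    """

    threshold: float
    clusters: list[frozenset[str]]
    singletons: frozenset[str]

    def __post_init__(self) -> None:
        if any(len(c) < 2 for c in self.clusters):
            raise ValueError("clusters must have size >= 2")

    @property
    def genes(self) -> frozenset[str]:
        out = set(self.singletons)
        for c in self.clusters:
            out |= c
        return frozenset(out)


@dataclass
class HierarchicalTree:
    """Agglomerative merge tree with heights normalized to [0, 1]."""

    genes: list[str]
    linkage_matrix: np.ndarray  # scipy format, heights already normalized

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.linkage_matrix.shape[0] != n - 1:
            raise ValueError("expected n-1 merges")
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")


def hac_cluster(sim: GeneSimMatrix, linkage: str = "average") -> HierarchicalTree:
    """Agglomerative clustering of 1 - similarity under the given linkage.

    Heights are rescaled by the root merge height so the tree spans
    leaves (0) to root (1) regardless of the similarity scale; a matrix
    of all-identical genes (root height 0) keeps heights at 0.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = sim.values
    if not np.allclose(values, values.T):
        raise ValueError("similarity matrix must be symmetric")
    if len(sim.genes) < 2:
        raise ValueError("need at least two genes")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    z = z.copy()
    root_height = z[-1, 2]
    if root_height > 0:
        z[:, 2] = z[:, 2] / root_height
    return HierarchicalTree(genes=list(sim.genes), linkage_matrix=z)


def cut_tree(tree: HierarchicalTree, thresholds: list[float] | None = None) -> list[ClusterSet]:
    """Cut the normalized tree at each threshold.

    Clusters at height h are the connected components of merges with
    height <= h; components of size 1 are reported as singletons.
    """
    thresholds = thresholds if thresholds is not None else default_thresholds()
    out = []
    for h in thresholds:
        labels = hierarchy.fcluster(tree.linkage_matrix, t=h, criterion="distance")
        groups: dict[int, set[str]] = {}
        for gene, lab in zip(tree.genes, labels):
            groups.setdefault(int(lab), set()).add(gene)
        clusters = [frozenset(g) for g in groups.values() if len(g) >= 2]
        singles = frozenset(next(iter(g)) for g in groups.values() if len(g) == 1)
        out.append(ClusterSet(threshold=h,
                              clusters=sorted(clusters, key=lambda c: (len(c), sorted(c))),
                              singletons=singles))
    return out


@dataclass
class InferredDAG:
    """DAG of gene modules from the clique threshold sweep.

    Each term is a gene set with the similarity cutoff at which it first
    appeared; containment edges run child -> parent, and cutoffs are
    non-increasing from leaves toward the root term of all genes.
    """

    genes: list[str]
    terms: list[tuple[frozenset[str], float]]  # (gene set, creation cutoff)
    edges: list[tuple[int, int]] = field(default_factory=list)  # child idx -> parent idx

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            cset, ccut = self.terms[child]
            pset, pcut = self.terms[parent]
            if not cset <= pset:
                raise ValueError("containment violated: child term not a subset of parent")
            if ccut < pcut:
                raise ValueError("creation cutoffs must be non-increasing toward the root")


def clixo_cluster(sim: GeneSimMatrix, alpha: float = 0.05, beta: float = 0.5,
                  max_genes: int = 200) -> InferredDAG:
    """Clique-based DAG inference by sweeping the similarity cutoff down.

    From max(sim) down to 0 in steps of ``alpha``: build the graph of
    gene pairs with similarity >= cutoff, enumerate its maximal cliques
    (size >= 2), and accept each clique as a new term unless it
    duplicates an existing term's gene set, or its Jaccard overlap with a
    term already accepted *at this cutoff* is >= ``beta`` (then it is
    merged — absorbed into that earlier, larger term, which stands for
    both).  Terms from higher cutoffs become children of the containing
    new terms.  The sweep always ends with a root term of all genes (at
    cutoff 0 the graph is complete).

    Overlap merging is restricted to same-cutoff candidates so that a
    module does not swallow its own sub-modules discovered at tighter
    cutoffs; those become children instead.  Because every term is a
    maximal clique of its creation-cutoff graph, a term created at a
    lower cutoff can never be a subset of an earlier term, so creation
    cutoffs are non-increasing from the leaves toward the root.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    genes = list(sim.genes)
    n = len(genes)
    if n > max_genes:
        raise ValueError(
            f"{n} genes exceeds the clique-enumeration budget of {max_genes}; "
            "use a smaller fixture")
    values = sim.values
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("similarities must be in [0, 1]")

    terms: list[tuple[frozenset[str], float]] = []
    seen: dict[frozenset[str], int] = {}
    cutoff = float(np.max(values[np.triu_indices(n, k=1)])) if n > 1 else 0.0
    all_genes = frozenset(genes)
    while True:
        cutoff = max(cutoff, 0.0)
        g = nx.Graph()
        g.add_nodes_from(genes)
        for i, j in itertools.combinations(range(n), 2):
            if values[i, j] >= cutoff:
                g.add_edge(genes[i], genes[j])
        cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= 2]
        # canonical order: larger cliques first, then lexicographic gene lists
        cliques.sort(key=lambda c: (-len(c), sorted(c)))
        accepted_here: list[int] = []
        for clique in cliques:
            if clique in seen:
                continue
            merged = False
            for idx in accepted_here:
                tset, _ = terms[idx]
                jac = len(clique & tset) / len(clique | tset)
                if jac >= beta:
                    merged = True  # absorbed into the earlier, larger term
                    break
            if not merged:
                terms.append((clique, cutoff))
                seen[clique] = len(terms) - 1
                accepted_here.append(len(terms) - 1)
        if all_genes in seen or cutoff == 0.0:
            break
        cutoff -= alpha
    if all_genes not in seen:  # every pair tied at cutoff 0 already handled above
        terms.append((all_genes, 0.0))

    edges = _containment_edges(terms)
    return InferredDAG(genes=genes, terms=terms, edges=edges)


def _containment_edges(terms: list[tuple[frozenset[str], float]]) -> list[tuple[int, int]]:
    """Transitive-reduction containment edges child -> parent."""
    edges = []
    for i, (si, _) in enumerate(terms):
        parents = [j for j, (sj, _) in enumerate(terms) if i != j and si < sj]
        # keep only minimal parents (no intermediate container)
        for j in parents:
            sj = terms[j][0]
            if not any(terms[k][0] < sj for k in parents if k != j and si < terms[k][0]):
                edges.append((i, j))
    return edges


def dag_clusters_at_thresholds(dag: InferredDAG,
                               thresholds: list[float] | None = None) -> list[ClusterSet]:
    """Map the inferred DAG onto the HAC threshold scale.

    For threshold h on the leaves(0) -> root(1) orientation, qualifying
    terms are those created at similarity cutoff >= 1 - h; of these only
    the containment-maximal ones are reported as clusters, so fine
    modules appear at small h and the all-gene root at h = 1.  Genes in
    no qualifying term are singletons.
    """
    thresholds = thresholds if thresholds is not None else default_thresholds()
    out = []
    all_genes = frozenset(dag.genes)
    for h in thresholds:
        qual = [(s, c) for s, c in dag.terms if c >= (1.0 - h) - 1e-12]
        sets = [s for s, _ in qual]
        maximal = [s for s in sets if not any(s < other for other in sets)]
        # dedupe while preserving deterministic order
        maximal = sorted(set(maximal), key=lambda c: (len(c), sorted(c)))
        covered: set[str] = set()
        for s in maximal:
            covered |= s
        out.append(ClusterSet(threshold=h, clusters=maximal,
                              singletons=frozenset(all_genes - covered)))
    return out


def write_cluster_sets(cluster_sets: list[ClusterSet], path: str) -> None:
    """TSV export: threshold, cluster ID, gene; singletons get ID 'singleton'."""
    with open(path, "w") as fh:
        fh.write("threshold\tcluster\tgene\n")
        for cs in cluster_sets:
            for k, cluster in enumerate(cs.clusters):
                for gene in sorted(cluster):
                    fh.write(f"{cs.threshold:g}\tC{k}\t{gene}\n")
            for gene in sorted(cs.singletons):
                fh.write(f"{cs.threshold:g}\tsingleton\t{gene}\n")


def write_inferred_dag(dag: InferredDAG, path: str) -> None:
    """3-column ontology edge format (parent, child, relation) for interchange."""
    with open(path, "w") as fh:
        for child, parent in dag.edges:
            fh.write(f"T{parent}\tT{child}\tis_a\n")
        for i, (s, _) in enumerate(dag.terms):
            for gene in sorted(s):
                fh.write(f"T{i}\t{gene}\tgene\n")
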