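"""Synthetic ontologies and annotation corpora with planted class structure.

Everything downstream — similarity, clustering, the incompleteness
simulation and its evaluation — runs on these fixtures without any
external download.  The generator plants a known class structure: the
ontology is a rooted DAG whose level-1 terms head disjoint class
subtrees, each gene gets a home class, and annotations are drawn from
the home subtree with probability ``class_coherence`` (else uniformly
from the whole ontology).  The planted gene classes are the ground
truth that per-class ROC/AUC evaluation scores against.

Two named regimes mirror the contrast between cellular processes
(shallower annotation loss, 1-8 annotations per gene) and multicellular
organism processes (heavier loss, 5-25 annotations per gene); their
missing-annotation counts follow a truncated geometric on 0..69, the
simplest monotone long-tailed family matching the observed shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import AnnotationSet, remove_redundant
from .incompleteness import MAX_MISSING, MissingCountDistribution
from .ontology import OntologyDAG, build_dag

ROOT = "T:0000"


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study fixture.

    ``annotations_per_gene`` is an inclusive integer range;
    ``missing_dist_shape`` is the success probability of the truncated
    geometric over missing counts 0..69 (larger -> fewer missing).
    """

    n_genes: int = 40
    n_leaf_classes: int = 5
    depth: int = 4
    branching: int = 2
    multi_parent_prob: float = 0.2
    annotations_per_gene: tuple[int, int] = (1, 8)
    class_coherence: float = 0.9
    missing_dist_shape: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.branching < 1:
            raise ValueError("branching must be >= 1")
        for p in (self.multi_parent_prob, self.class_coherence):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 < self.missing_dist_shape <= 1:
            raise ValueError("missing_dist_shape must be in (0, 1]")
        lo, hi = self.annotations_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("annotations_per_gene must be a range with lo >= 1")


def cellular_config(**overrides) -> SyntheticConfig:
    """Cellular-process-like regime: few annotations, mild incompleteness."""
    return replace(SyntheticConfig(annotations_per_gene=(1, 8),
                                   missing_dist_shape=0.5), **overrides)


def multicellular_config(**overrides) -> SyntheticConfig:
    """Multicellular-process-like regime: many annotations, heavy incompleteness.

    The deeper, wider per-class subtree (depth 5, branching 3: 40 terms,
    27 leaves) gives the larger annotation sets room to stay
    non-redundant, mirroring the richer multicellular branch of the
    ontology.
    """
    return replace(SyntheticConfig(annotations_per_gene=(5, 25),
                                   missing_dist_shape=0.13, depth=5, branching=3),
                   **overrides)


def generate_ontology(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> OntologyDAG:
    """Rooted DAG of the configured depth with tagged leaf-class subtrees.

    Level 1 holds one class-head term per leaf class; below that each
    term has ``branching`` is_a children down to the configured depth.  Terms at
    level >= 2 acquire a second (part_of) parent with probability
    ``multi_parent_prob``, drawn from a strictly shallower level so the
    graph stays acyclic.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    edges: list[tuple[str, str, str]] = []
    levels: dict[int, list[str]] = {0: [ROOT]}
    class_heads: dict[str, str] = {}
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"T:{counter:04d}"

    for k in range(cfg.n_leaf_classes):
        head = new_term()
        class_heads[head] = f"class{k}"
        edges.append((head, ROOT, "is_a"))
        levels.setdefault(1, []).append(head)
        frontier = [head]
        for level in range(2, cfg.depth):
            nxt = []
            for parent in frontier:
                for _ in range(cfg.branching):
                    child = new_term()
                    edges.append((child, parent, "is_a"))
                    nxt.append(child)
            levels.setdefault(level, []).extend(nxt)
            frontier = nxt
    for level in sorted(levels):
        if level < 2:
            continue
        for term in levels[level]:
            if rng.random() < cfg.multi_parent_prob:
                primary = next(p for c, p, _ in edges if c == term)
                shallower = [t for lv in range(1, level) for t in levels[lv]
                             if t != primary]
                if shallower:
                    second = shallower[rng.integers(len(shallower))]
                    edges.append((term, second, "part_of"))
    terms = {ROOT} | {c for c, _, _ in edges}
    return build_dag(edges, terms=terms, class_heads=class_heads)


def _class_subtrees(dag: OntologyDAG) -> dict[str, list[str]]:
    """Terms reachable downward from each class head (is_a children only)."""
    import networkx as nx
    isa = nx.DiGraph()
    isa.add_nodes_from(dag.graph.nodes)
    isa.add_edges_from((u, v) for u, v, d in dag.graph.edges(data=True)
                       if d["relation"] == "is_a")
    subtrees: dict[str, list[str]] = {}
    for head, class_id in dag.class_heads.items():
        # isa edges run child -> parent, so the subtree below `head` is the
        # set of nodes with a path to it
        subtrees[class_id] = sorted(nx.ancestors(isa, head) | {head})
    return subtrees


def generate_annotations(dag: OntologyDAG, cfg: SyntheticConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[AnnotationSet, dict[str, frozenset[str]]]:
    """Complete annotation set with planted class coherence.

    Genes are spread evenly over the leaf classes (class sizes must land
    in the 5-50 window used by the evaluation).  Each gene draws its
    annotation count from ``annotations_per_gene`` and each annotation
    from its home-class subtree with probability ``class_coherence``,
    else uniformly from all non-root terms.  The result is
    redundancy-reduced, so it is a fixed point of remove_redundant.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    subtrees = _class_subtrees(dag)
    class_ids = sorted(subtrees)
    base, extra = divmod(cfg.n_genes, len(class_ids))
    sizes = {cid: base + (1 if i < extra else 0) for i, cid in enumerate(class_ids)}
    for cid, size in sizes.items():
        if not 5 <= size <= 50:
            raise ValueError(
                f"planted class {cid} would have {size} genes, outside the 5-50 "
                "window the evaluation scores; adjust n_genes/n_leaf_classes")
    non_root = sorted(dag.terms - {dag.root})
    annotations: dict[str, set[str]] = {}
    classes: dict[str, set[str]] = {cid: set() for cid in class_ids}
    gene_no = 0
    for cid in class_ids:
        home = subtrees[cid]
        for _ in range(sizes[cid]):
            gene = f"g{gene_no:03d}"
            gene_no += 1
            classes[cid].add(gene)
            lo, hi = cfg.annotations_per_gene
            count = int(rng.integers(lo, hi + 1))
            terms: set[str] = set()
            for _ in range(count):
                if rng.random() < cfg.class_coherence:
                    terms.add(home[rng.integers(len(home))])
                else:
                    terms.add(non_root[rng.integers(len(non_root))])
            annotations[gene] = terms
    ann = remove_redundant(AnnotationSet(annotations, dag))
    return ann, {cid: frozenset(gs) for cid, gs in classes.items()}


def generate_missing_dist(cfg: SyntheticConfig, n_genes: int,
                          rng: np.random.Generator | None = None
                          ) -> MissingCountDistribution:
    """Per-gene missing counts from a geometric truncated to 0..69."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    draws = rng.geometric(cfg.missing_dist_shape, size=n_genes) - 1
    draws = np.minimum(draws, MAX_MISSING)
    return MissingCountDistribution.from_counts(draws.tolist())


@dataclass
class StudyFixture:
    """Everything one end-to-end run needs, generated from a single seed."""

    ontology: OntologyDAG
    annotations: AnnotationSet
    classes: dict[str, frozenset[str]]
    missing_dist: MissingCountDistribution
    config: SyntheticConfig


def generate_study_fixture(cfg: SyntheticConfig) -> StudyFixture:
    """One-call bundle: ontology, complete annotations, classes, missing dist."""
    rng = np.random.default_rng(cfg.seed)
    dag = generate_ontology(cfg, rng)
    ann, classes = generate_annotations(dag, cfg, rng)
    dist = generate_missing_dist(cfg, n_genes=cfg.n_genes, rng=rng)
    return StudyFixture(ontology=dag, annotations=ann, classes=classes,
                        missing_dist=dist, config=cfg)


def write_classes(classes: dict[str, frozenset[str]], path: str) -> None:
    """TSV export: class, gene."""
    with open(path, "w") as fh:
        fh.write("class\tgene\n")
        for cid in sorted(classes):
            for gene in sorted(classes[cid]):
                fh.write(f"{cid}\t{gene}\n")


def read_classes(path: str) -> dict[str, frozenset[str]]:
    classes: dict[str, set[str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, gene = line.rstrip("\n").split("\t")
            classes.setdefault(cid, set()).add(gene)
    return {cid: frozenset(gs) for cid, gs in classes.items()}


def write_annotations_tsv(ann: AnnotationSet, path: str) -> None:
    """GAF-like TSV export: gene, term (one row per annotation)."""
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in ann.genes:
            for term in sorted(ann.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
            if not ann.annotations[gene]:
                fh.write(f"{gene}\t-\n")


def read_annotations_tsv(path: str, dag: OntologyDAG) -> AnnotationSet:
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            gene, term = line.rstrip("\n").split("\t")
            annotations.setdefault(gene, set())
            if term != "-":
                annotations[gene].add(term)
    return AnnotationSet(annotations, dag)
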