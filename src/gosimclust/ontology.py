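"""Rooted DAG representation of an ontology with is_a / part_of edges.

The ontology backbone everything else builds on: ancestor closures feed
redundancy removal, information content and most-informative-common-ancestor
lookups. Only ``is_a`` and ``part_of`` relations are kept; other relation
types (``regulates`` etc.) are counted and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

KEPT_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyDAG:
    """Rooted directed acyclic graph of terms.

    Edges point child -> parent and carry a relation label, either
    ``is_a`` or ``part_of``.  Exactly one root (a term with no parents)
    is designated; every other term reaches it.
    """

    graph: nx.DiGraph
    root: str
    #: leaf-class tags set by the synthetic generator (class head term -> class id)
    class_heads: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        self._closure_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive closure over is_a/part_of, excluding ``term`` itself."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term}")
        cached = self._closure_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._closure_cache[term] = cached
        return cached

    def closure(self, term: str) -> frozenset[str]:
        """Ancestors plus the term itself."""
        return self.ancestors(term) | {term}

    def is_ancestor(self, anc: str, term: str) -> bool:
        return anc in self.ancestors(term)


def build_dag(edges: list[tuple[str, str, str]], terms: set[str] | None = None,
              class_heads: dict[str, str] | None = None) -> OntologyDAG:
    """Construct an :class:`OntologyDAG` from (child, parent, relation) triples.

    Convenience constructor used by tests and the synthetic generator.
    """
    g = nx.DiGraph()
    if terms:
        g.add_nodes_from(terms)
    for child, parent, rel in edges:
        if rel not in KEPT_RELATIONS:
            raise ValueError(f"unsupported relation {rel!r}")
        g.add_edge(child, parent, relation=rel)
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {roots}")
    return OntologyDAG(graph=g, root=roots[0], class_heads=dict(class_heads or {}))


def read_obo(path: str) -> OntologyDAG:
    """Read an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Keeps ``is_a`` and ``relationship: part_of`` edges; every other
    relationship type is dropped with a logged count.  Obsolete terms are
    absent (obonet already excludes them).  If several namespace roots are
    present, terms outside the largest rooted component are dropped.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    ignored = 0
    for child, parent, key in multi.edges(keys=True):
        if key in KEPT_RELATIONS:
            g.add_edge(child, parent, relation=key)
        else:
            ignored += 1
    if ignored:
        logger.info("read_obo: ignored %d edges with unsupported relation types", ignored)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cycle detected in ontology: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if not roots:
        raise ValueError("ontology has no root term")
    if len(roots) > 1:
        # one designated root per namespace: keep the largest rooted component
        best = max(roots, key=lambda r: (len(nx.ancestors(g, r)), r))
        keep = nx.ancestors(g, best) | {best}
        dropped = set(g.nodes) - keep
        logger.warning("read_obo: %d roots found; keeping %r and dropping %d terms",
                       len(roots), best, len(dropped))
        g = g.subgraph(keep).copy()
        root = best
    else:
        root = roots[0]
    return OntologyDAG(graph=g, root=root)


def write_obo(dag: OntologyDAG, path: str) -> None:
    """Write a minimal OBO 1.2 rendering of the DAG (round-trips via read_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for child, parent, data in sorted(dag.graph.out_edges(term, data=True)):
                rel = data["relation"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")
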