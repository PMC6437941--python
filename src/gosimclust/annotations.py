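"""Gene -> GO-term annotation sets, information content and MICA.

An :class:`AnnotationSet` maps each gene to the set of terms it is
annotated to.  Before any similarity is computed the set is made
non-redundant: an annotation to a term that is an ancestor of another
annotated term of the same gene carries no extra information and is
removed.

Information content follows the gene-counting convention: p(t) is the
fraction of annotated genes annotated to t *or any of its descendants*,
and IC(t) = -ln p(t), so the root always has p = 1 and IC = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

#: experimental evidence codes used to build "complete" annotation corpora
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IGI", "IEP", "IMP"})


@dataclass
class AnnotationSet:
    """Mapping gene -> set of term IDs against one ontology.

    Genes whose annotations were all removed (e.g. by the incompleteness
    simulator) stay in the mapping with an empty set; downstream analyses
    apply the at-least-one-annotation filter in exactly one place
    (:meth:`annotated_genes`).
    """

    annotations: dict[str, set[str]]
    ontology: OntologyDAG

    def __post_init__(self) -> None:
        for gene, terms in self.annotations.items():
            unknown = {t for t in terms if t not in self.ontology}
            if unknown:
                raise ValueError(f"gene {gene} annotated to unknown terms {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def annotated_genes(self) -> list[str]:
        """Genes with at least one annotation, the analysis universe."""
        return sorted(g for g, ts in self.annotations.items() if ts)

    def unannotated_genes(self) -> list[str]:
        return sorted(g for g, ts in self.annotations.items() if not ts)

    def __getitem__(self, gene: str) -> set[str]:
        return self.annotations[gene]

    def __len__(self) -> int:
        return len(self.annotations)

    def copy(self) -> "AnnotationSet":
        return AnnotationSet({g: set(ts) for g, ts in self.annotations.items()}, self.ontology)

    def is_subset_of(self, other: "AnnotationSet") -> bool:
        return all(ts <= other.annotations.get(g, set()) for g, ts in self.annotations.items())


def read_gaf(path: str, ontology: OntologyDAG,
             evidence_filter: frozenset[str] = EXPERIMENTAL_EVIDENCE) -> AnnotationSet:
    """Read a GAF 2.x file, keeping rows with an allowed evidence code.

    Columns used: 2 (gene symbol), 4 (qualifier, NOT rows dropped),
    5 (term), 7 (evidence code).  Duplicate (gene, term) pairs — e.g. the
    same annotation supported by different papers — collapse to one
    annotation.  Rows whose term is absent from the ontology are dropped
    with a logged warning.
    """
    ann: dict[str, set[str]] = {}
    dropped_terms = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                continue
            gene, qualifier, term, evidence = cols[2], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence not in evidence_filter:
                continue
            if term not in ontology:
                dropped_terms += 1
                continue
            ann.setdefault(gene, set()).add(term)
    if dropped_terms:
        logger.warning("read_gaf: dropped %d rows with terms absent from ontology", dropped_terms)
    return AnnotationSet(ann, ontology)


def remove_redundant(ann: AnnotationSet) -> AnnotationSet:
    """Drop, per gene, any annotated term that is an ancestor of another.

    The more specific annotation implies the less specific one, so only
    the most specific terms are kept.  Idempotent.
    """
    dag = ann.ontology
    reduced: dict[str, set[str]] = {}
    for gene, terms in ann.annotations.items():
        ancestors_of_any: set[str] = set()
        for t in terms:
            ancestors_of_any |= dag.ancestors(t)
        reduced[gene] = {t for t in terms if t not in ancestors_of_any}
    return AnnotationSet(reduced, dag)


@dataclass
class ICTable:
    """Term probabilities and information content for one corpus.

    Only terms that actually occur in the corpus closure get an entry;
    asking for the similarity of an unused term is an error, not an
    imputed value.
    """

    prob: dict[str, float]
    ic: dict[str, float]
    ontology: OntologyDAG = field(repr=False)

    @property
    def ic_max(self) -> float:
        return max(self.ic.values())

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def compute_ic(ann: AnnotationSet) -> ICTable:
    """Gene-counting information content over a redundancy-reduced corpus.

    p(t) = (# genes annotated to t or a descendant of t) / (# annotated
    genes); IC(t) = -ln p(t).  The root is always covered by every
    annotated gene's closure, so p(root) = 1 and IC(root) = 0.
    """
    genes = ann.annotated_genes()
    if not genes:
        raise ValueError("cannot compute IC on an empty corpus")
    dag = ann.ontology
    counts: dict[str, int] = {}
    for gene in genes:
        closure: set[str] = set()
        for t in ann.annotations[gene]:
            closure |= dag.closure(t)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    n = len(genes)
    prob = {t: c / n for t, c in counts.items()}
    ic = {t: -math.log(p) for t, p in prob.items()}
    return ICTable(prob=prob, ic=ic, ontology=dag)


def mica(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms.

    The search space includes the query terms themselves, so
    mica(t, t) = (t, IC(t)).  Ties on IC break to the lexicographically
    smallest term ID for determinism.
    """
    if t1 not in ic or t2 not in ic:
        missing = [t for t in (t1, t2) if t not in ic]
        raise KeyError(f"terms without IC entries: {missing}")
    common = (dag.closure(t1) & dag.closure(t2)) & set(ic.ic)
    if not common:
        raise ValueError(f"no common ancestor for {t1} and {t2}")
    best = min(common, key=lambda t: (-ic.ic[t], t))
    return best, ic.ic[best]


def write_ic_table(ic: ICTable, path: str) -> None:
    """TSV export: term, p, IC."""
    with open(path, "w") as fh:
        fh.write("term\tp\tic\n")
        for term in sorted(ic.ic):
            fh.write(f"{term}\t{ic.prob[term]:.10g}\t{ic.ic[term]:.10g}\n")
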