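"""The 14 gene-level functional similarity measures.

Twelve are (term measure x combiner): {Resnik, Lin, Jiang-Conrath,
Relevance} x {MAX, BMA, AVG}.  Two are inherently gene-level vector
measures over IC-weighted ancestral closures: weighted cosine and
weighted Jaccard.  Every measure returns values in [0, 1].

Conventions (configurable where noted):

* Resnik is normalized by the corpus-maximal IC so it lands in [0, 1];
  the raw-IC variant is available via ``resnik_normalize=False``.
* Jiang-Conrath distance d = IC(t1)+IC(t2)-2 IC(mica) is converted to a
  similarity by 1/(1+d); the alternative 1 - min(1, d/d_max) is exposed
  via ``jc_transform="linear"``.
* Degenerate Lin/Relevance with IC(t1)+IC(t2) = 0 is 1 when t1 == t2,
  else 0, avoiding 0/0 at the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet, ICTable, mica
from .ontology import OntologyDAG

TERM_MEASURES = ("resnik", "lin", "jiang_conrath", "relevance")
COMBINERS = ("MAX", "BMA", "AVG")
VECTOR_MEASURES = ("weighted_cosine", "weighted_jaccard")


@dataclass(frozen=True)
class MeasureSpec:
    """One of the 14 valid gene-level measure combinations."""

    term_measure: str = "none"
    combiner: str = "none"
    vector_measure: str = "none"

    def __post_init__(self) -> None:
        ic_based = self.term_measure in TERM_MEASURES and self.combiner in COMBINERS
        vector = self.vector_measure in VECTOR_MEASURES
        if ic_based == vector:
            raise ValueError(
                "exactly one of (term_measure + combiner) or vector_measure must be set; "
                f"got {self}")
        if ic_based and self.vector_measure != "none":
            raise ValueError(f"vector_measure must be 'none' for IC-based specs: {self}")
        if vector and (self.term_measure != "none" or self.combiner != "none"):
            raise ValueError(f"term_measure/combiner must be 'none' for vector specs: {self}")

    @property
    def name(self) -> str:
        if self.vector_measure != "none":
            return self.vector_measure
        return f"{self.term_measure}_{self.combiner}"

    @classmethod
    def from_name(cls, name: str) -> "MeasureSpec":
        if name in VECTOR_MEASURES:
            return cls(vector_measure=name)
        measure, _, combiner = name.rpartition("_")
        return cls(term_measure=measure, combiner=combiner)


def all_measure_specs() -> list[MeasureSpec]:
    """The full factorial of 14 gene-level measures."""
    specs = [MeasureSpec(term_measure=m, combiner=c)
             for m in TERM_MEASURES for c in COMBINERS]
    specs += [MeasureSpec(vector_measure=v) for v in VECTOR_MEASURES]
    return specs


def term_sim(measure: str, t1: str, t2: str, ic: ICTable, dag: OntologyDAG,
             resnik_normalize: bool = True, jc_transform: str = "reciprocal") -> float:
    """Pairwise term semantic similarity in [0, 1] (raw Resnik excepted)."""
    if measure not in TERM_MEASURES:
        raise ValueError(f"unknown term measure {measure!r}")
    mica_term, ic_mica = mica(dag, ic, t1, t2)
    ic1, ic2 = ic.ic[t1], ic.ic[t2]

    if measure == "resnik":
        if not resnik_normalize:
            return ic_mica
        if ic.ic_max == 0:
            raise ValueError("cannot normalize Resnik: corpus-maximal IC is 0")
        return ic_mica / ic.ic_max

    if measure in ("lin", "relevance"):
        if ic1 + ic2 == 0:
            lin = 1.0 if t1 == t2 else 0.0
        else:
            lin = 2.0 * ic_mica / (ic1 + ic2)
        if measure == "lin":
            return lin
        return lin * (1.0 - ic.prob[mica_term])

    # jiang_conrath
    d = ic1 + ic2 - 2.0 * ic_mica
    if jc_transform == "reciprocal":
        return 1.0 / (1.0 + d)
    if jc_transform == "linear":
        d_max = 2.0 * ic.ic_max
        if d_max == 0:
            return 1.0
        return 1.0 - min(1.0, d / d_max)
    raise ValueError(f"unknown jc_transform {jc_transform!r}")


def combine(combiner: str, termsims: np.ndarray) -> float:
    """Collapse an m x n matrix of annotation-pair similarities to one score.

    MAX takes the single best pair; AVG averages all m*n pairs (and is
    therefore diluted by the N(N-1)/2 mismatching pairs of two genes with
    N matching annotations each); BMA averages the two directional
    best-match means.
    """
    ts = np.asarray(termsims, dtype=float)
    if ts.ndim != 2 or ts.size == 0:
        raise ValueError("termsims must be a non-empty 2-D matrix "
                         "(genes without annotations are excluded from analysis)")
    if combiner == "MAX":
        return float(ts.max())
    if combiner == "AVG":
        return float(ts.mean())
    if combiner == "BMA":
        return float(0.5 * (ts.max(axis=1).mean() + ts.max(axis=0).mean()))
    raise ValueError(f"unknown combiner {combiner!r}")


def _closure_vector(gene: str, ann: AnnotationSet, ic: ICTable,
                    term_index: dict[str, int]) -> np.ndarray:
    v = np.zeros(len(term_index))
    dag = ann.ontology
    closure: set[str] = set()
    for t in ann.annotations[gene]:
        closure |= dag.closure(t)
    for t in closure:
        if t in ic:
            v[term_index[t]] = ic.ic[t]
    return v


def vector_sim(measure: str, gene_x: str, gene_y: str,
               ann: AnnotationSet, ic: ICTable) -> float:
    """Weighted cosine / weighted Jaccard over IC-weighted closures.

    Each gene becomes a vector over annotated terms plus their ancestors
    with weight IC(t); the root has weight 0 and so never contributes.
    A gene whose closure carries no IC mass (only the root) has
    similarity 0 to everything by convention.
    """
    if measure not in VECTOR_MEASURES:
        raise ValueError(f"unknown vector measure {measure!r}")
    if not ann.annotations[gene_x] or not ann.annotations[gene_y]:
        raise ValueError("both genes must have at least one annotation")
    term_index = {t: i for i, t in enumerate(sorted(ic.ic))}
    vx = _closure_vector(gene_x, ann, ic, term_index)
    vy = _closure_vector(gene_y, ann, ic, term_index)
    return _vector_sim_arrays(measure, vx, vy)


def _vector_sim_arrays(measure: str, vx: np.ndarray, vy: np.ndarray) -> float:
    nx_, ny_ = np.linalg.norm(vx), np.linalg.norm(vy)
    if nx_ == 0 or ny_ == 0:
        return 0.0
    if measure == "weighted_cosine":
        return float(np.dot(vx, vy) / (nx_ * ny_))
    denom = np.maximum(vx, vy).sum()
    return float(np.minimum(vx, vy).sum() / denom)


@dataclass
class GeneSimMatrix:
    """Symmetric gene x gene similarity matrix under one measure spec.

    The diagonal is fixed at 1 by definition (a gene is functionally
    identical to itself); note this is *not* the AVG combiner's score for
    two distinct genes with identical annotation sets, which is diluted
    to 1/N for N mutually dissimilar annotations.
    """

    genes: list[str]
    values: np.ndarray
    spec: MeasureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")
        # clamp float roundoff so downstream range checks are exact
        self.values = np.clip(self.values, 0.0, 1.0)

    def sim(self, gx: str, gy: str) -> float:
        i, j = self.genes.index(gx), self.genes.index(gy)
        return float(self.values[i, j])


class TermSimCache:
    """Precomputed term x term similarity over the annotated-term set.

    One MICA table is shared across the four IC-based measures; combine()
    then works on numpy slices, which keeps the full factorial of 14
    measures x many replicates affordable.
    """

    def __init__(self, ann: AnnotationSet, ic: ICTable):
        self.ann = ann
        self.ic = ic
        self.dag = ann.ontology
        used: set[str] = set()
        for terms in ann.annotations.values():
            used |= terms
        self.terms = sorted(t for t in used if t in ic)
        self.index = {t: i for i, t in enumerate(self.terms)}
        self._matrices: dict[str, np.ndarray] = {}

    def matrix(self, measure: str) -> np.ndarray:
        m = self._matrices.get(measure)
        if m is None:
            k = len(self.terms)
            m = np.zeros((k, k))
            for i, t1 in enumerate(self.terms):
                for j in range(i, k):
                    t2 = self.terms[j]
                    s = term_sim(measure, t1, t2, self.ic, self.dag)
                    m[i, j] = m[j, i] = s
            self._matrices[measure] = m
        return m


def gene_sim_matrix(ann: AnnotationSet, spec: MeasureSpec, ic: ICTable,
                    cache: TermSimCache | None = None) -> GeneSimMatrix:
    """Full pairwise gene similarity matrix under one measure spec.

    Genes without annotations, and genes annotated only to terms absent
    from the IC table, are excluded from the matrix.
    """
    genes = [g for g in ann.annotated_genes()
             if any(t in ic for t in ann.annotations[g])]
    if len(genes) < 2:
        raise ValueError("need at least two annotated genes")
    n = len(genes)
    values = np.eye(n)

    if spec.vector_measure != "none":
        term_index = {t: i for i, t in enumerate(sorted(ic.ic))}
        vectors = np.array([_closure_vector(g, ann, ic, term_index) for g in genes])
        for i in range(n):
            for j in range(i + 1, n):
                s = _vector_sim_arrays(spec.vector_measure, vectors[i], vectors[j])
                values[i, j] = values[j, i] = s
    else:
        if cache is None:
            cache = TermSimCache(ann, ic)
        tmat = cache.matrix(spec.term_measure)
        idx = [np.array([cache.index[t] for t in ann.annotations[g] if t in cache.index])
               for g in genes]
        for i in range(n):
            for j in range(i + 1, n):
                block = tmat[np.ix_(idx[i], idx[j])]
                s = combine(spec.combiner, block)
                values[i, j] = values[j, i] = s
    return GeneSimMatrix(genes=genes, values=values, spec=spec)


def write_sim_matrix(mat: GeneSimMatrix, path: str) -> None:
    """TSV interchange format: header row/column of gene IDs, full matrix."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(mat.genes) + "\n")
        for i, g in enumerate(mat.genes):
            row = "\t".join(f"{v:.10g}" for v in mat.values[i])
            fh.write(f"{g}\t{row}\n")


def read_sim_matrix(path: str, spec: MeasureSpec | None = None) -> GeneSimMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    spec = spec or MeasureSpec(term_measure="lin", combiner="MAX")
    return GeneSimMatrix(genes=header, values=np.array(rows), spec=spec)
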