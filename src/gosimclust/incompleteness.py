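"""Quantifying and simulating annotation incompleteness.

The missing-annotation count for a gene is estimated by comparing a
"complete" corpus (well-studied model-organism orthologs) against the
actual annotations of the mapped gene, clamped at zero.  The resulting
count distribution drives a removal procedure that degrades a complete
annotation set: working from the largest missing count n downward,
pick g_n untouched genes with at least n annotations and delete n
uniformly chosen annotations from each, so each gene is modified at
most once and the multiset of per-gene removal counts reproduces the
distribution whenever feasible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet

logger = logging.getLogger(__name__)

MAX_MISSING = 69  # per-gene missing counts are bounded: 0 <= n < 70


@dataclass
class MissingCountDistribution:
    """Multiset of per-gene missing-annotation counts.

    ``g[n]`` is the number of genes with n missing annotations; the
    support is the decreasing sequence of distinct n values the removal
    procedure iterates over.
    """

    g: dict[int, int]

    def __post_init__(self) -> None:
        for n, gn in self.g.items():
            if n < 0 or gn < 0:
                raise ValueError("counts must be non-negative")
            if n > MAX_MISSING:
                raise ValueError(f"missing count {n} exceeds the bound {MAX_MISSING}")
        self.g = {n: gn for n, gn in self.g.items() if gn > 0}

    @classmethod
    def from_counts(cls, counts: list[int]) -> "MissingCountDistribution":
        return cls(g=dict(Counter(counts)))

    @property
    def counts(self) -> list[int]:
        """The multiset of per-gene counts, as a sorted list."""
        out: list[int] = []
        for n in sorted(self.g):
            out.extend([n] * self.g[n])
        return out

    @property
    def n_genes(self) -> int:
        return sum(self.g.values())

    def mean(self) -> float:
        if self.n_genes == 0:
            return 0.0
        return sum(n * gn for n, gn in self.g.items()) / self.n_genes


def estimate_missing_counts(complete: AnnotationSet, actual: AnnotationSet,
                            ortholog_map: dict[str, str]) -> MissingCountDistribution:
    """Per-gene missing counts: |complete| - |actual ortholog|, floored at 0.

    Genes of the complete set without an ortholog mapping (or whose
    ortholog is absent from the actual set) are excluded with a log
    message; differences below zero — the mapped gene has *more*
    annotations than its well-studied ortholog — are set to 0.
    """
    counts = []
    skipped = 0
    for gene in complete.genes:
        mapped = ortholog_map.get(gene)
        if mapped is None or mapped not in actual.annotations:
            skipped += 1
            continue
        n = max(0, len(complete.annotations[gene]) - len(actual.annotations[mapped]))
        counts.append(min(n, MAX_MISSING))
    if skipped:
        logger.info("estimate_missing_counts: %d genes without usable ortholog mapping", skipped)
    return MissingCountDistribution.from_counts(counts)


def simulate_incomplete(complete: AnnotationSet, dist: MissingCountDistribution,
                        seed: int) -> AnnotationSet:
    """One random incomplete annotation set drawn from the removal procedure.

    Iterates n from the largest missing count down; at each n, g_n
    not-yet-modified genes with >= n annotations are selected uniformly
    without replacement and n of their annotations deleted uniformly.
    If fewer than g_n genes are eligible, all eligible genes are used
    and the shortfall carries to the next smaller n (logged); genes left
    with zero annotations are retained, flagged by their empty sets.
    """
    rng = np.random.default_rng(seed)
    result = complete.copy()
    unmodified = set(complete.genes)
    carry = 0
    for n in sorted(dist.g, reverse=True):
        needed = dist.g[n] + carry
        carry = 0
        if n == 0:
            break  # removing zero annotations is a no-op
        eligible = sorted(g for g in unmodified if len(result.annotations[g]) >= n)
        if len(eligible) < needed:
            carry = needed - len(eligible)
            logger.warning(
                "simulate_incomplete: only %d of %d genes eligible at n=%d; "
                "carrying shortfall of %d to smaller n", len(eligible), needed, n, carry)
            chosen = eligible
        else:
            chosen = sorted(rng.choice(eligible, size=needed, replace=False))
        for gene in chosen:
            terms = sorted(result.annotations[gene])
            drop = rng.choice(terms, size=n, replace=False)
            result.annotations[gene] -= set(drop.tolist())
            unmodified.discard(gene)
    if carry:
        logger.warning("simulate_incomplete: %d removal assignments could not be placed", carry)
    return result


@dataclass
class IncompleteSetCollection:
    """Replicated incomplete annotation sets from one master seed."""

    replicates: list[AnnotationSet]
    seed: int
    source: AnnotationSet = field(repr=False)

    def __len__(self) -> int:
        return len(self.replicates)


def simulate_collection(complete: AnnotationSet, dist: MissingCountDistribution,
                        reps: int = 100, seed: int = 0) -> IncompleteSetCollection:
    """``reps`` independent replicates with per-replicate seeds seed + index."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    replicates = [simulate_incomplete(complete, dist, seed=seed + i) for i in range(reps)]
    return IncompleteSetCollection(replicates=replicates, seed=seed, source=complete)


def removal_counts(complete: AnnotationSet, incomplete: AnnotationSet) -> list[int]:
    """Per-gene numbers of removed annotations, sorted (a tabulation aid)."""
    return sorted(len(complete.annotations[g]) - len(incomplete.annotations.get(g, set()))
                  for g in complete.genes)


def write_missing_dist(dist: MissingCountDistribution, path: str) -> None:
    """Two-column TSV: n, g_n."""
    with open(path, "w") as fh:
        fh.write("n\tg_n\n")
        for n in sorted(dist.g):
            fh.write(f"{n}\t{dist.g[n]}\n")


def read_missing_dist(path: str) -> MissingCountDistribution:
    g: dict[int, int] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            n, gn = line.split("\t")
            g[int(n)] = int(gn)
    return MissingCountDistribution(g=g)
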