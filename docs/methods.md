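# Methods

`gosimclust` evaluates how the choice of GO semantic-similarity measure,
gene-level scoring method, and clustering algorithm interact with the
incompleteness of annotation sets. The pipeline is: annotation corpus →
information content → 14 gene-level similarity matrices → two clusterings at
10 thresholds → simulated annotation loss → accuracy / consistency /
robustness scores. This note records the model and the choices made where
the design was genuinely open.

## Ontology, annotations, information content

The ontology is a rooted DAG with `is_a` and `part_of` edges (other relation
types are dropped with a logged count; regulates-style relations are out of
scope). Annotation sets map genes to term sets and are always
redundancy-reduced before analysis: an annotation to a term that is an
ancestor of another annotated term of the same gene is implied by it and is
removed. The reduction is idempotent and never empties a non-empty set.

Information content uses the gene-counting convention:

    p(t)  = #{genes annotated to t or a descendant of t} / #{annotated genes}
    IC(t) = −ln p(t)

so p(root) = 1, IC(root) = 0, and IC is non-decreasing from parent to child.
Two choices deserve note:

* **Natural logarithm.** Any fixed base rescales all ICs by a constant; the
  Lin and Relevance measures are IC ratios and Resnik is normalized by the
  corpus maximum, so the base is observationally irrelevant for those, and
  only raw (un-normalized) Resnik would show it.
* **Gene counting, not annotation-row counting.** p(t) is the fraction of
  genes whose annotation closure covers t. This is the convention of the
  established semantic-similarity tools and makes the root count conserve
  the number of annotated genes.

Terms never used in the corpus get no IC entry; asking for the similarity of
such a term is an error, not an imputed value. The MICA (most informative
common ancestor) search includes the query terms themselves, so
mica(t, t) = t; ties on IC break to the lexicographically smallest term ID
for determinism.

## The 14 gene-level measures

Term-level measures, all mapped into [0, 1]:

| measure | formula |
|---|---|
| Lin | 2·IC(mica) / (IC(t1) + IC(t2)) |
| Resnik (normalized) | IC(mica) / IC_max |
| Relevance | Lin(t1, t2) · (1 − p(mica)) |
| Jiang–Conrath | 1 / (1 + d), d = IC(t1) + IC(t2) − 2·IC(mica) |

Open choices, fixed as follows:

* **Resnik normalization** by the corpus-maximal IC keeps all similarity
  axes and clustering thresholds on the same 0–1 scale; the raw-IC variant
  is available via `resnik_normalize=False`.
* **Jiang–Conrath transform**: the bounded, monotone `1/(1+d)` equals 1 iff
  d = 0; the alternative `1 − min(1, d/d_max)` is exposed via
  `jc_transform="linear"`.
* **Degenerate Lin/Relevance** with IC(t1) + IC(t2) = 0 (both terms at the
  root) is defined as 1 when t1 = t2 and 0 otherwise, avoiding 0/0.

Gene-level combiners over the m×n matrix of annotation-pair similarities:
MAX (best single pair), AVG (all-pairs mean), and BMA as the symmetric
two-sided best-match average — the mean of row maxima averaged with the mean
of column maxima — which is the dominant published BMA convention and
symmetric by construction. AVG is deliberately *not* self-maximal: two genes
sharing N mutually dissimilar annotations score N matching pairs against
N(N−1)/2 mismatching pairs, i.e. exactly 1/N. This dilution is the
structural weakness of all-pairs averaging that the evaluation quantifies.
The similarity *matrix* diagonal is nevertheless fixed at 1 by definition
(a gene is functionally identical to itself); the dilution shows between
distinct genes.

The two inherently gene-level measures embed each gene as a vector over its
annotated terms plus all their ancestors, weighted by IC (the root weighs 0
and never contributes): weighted cosine is the normalized dot product and
weighted Jaccard is Σ min / Σ max over coordinates. A closure with no IC
mass has similarity 0 to everything.

Genes with no annotations are excluded from every similarity matrix — the
at-least-one-annotation filter is applied in exactly one place
(`AnnotationSet.annotated_genes`), so simulated genes stripped of all
annotations stay in the bookkeeping but leave the analysis universe.

## Clustering

**HAC**: agglomerative clustering of distance 1 − similarity (the only
transform keeping both scales in [0, 1]) under average linkage (UPGMA) by
default; single and complete linkage are available. Merge heights are
normalized by the root merge so thresholds run from the leaves (0) to the
root (1) for every matrix; a matrix of all-identical genes keeps heights at
0. Cluster sets at a threshold h are the connected components of merges with
height ≤ h; size-1 components are singletons.

**Clique-DAG clustering** sweeps a similarity cutoff from max(sim) down to 0
in steps of `alpha` (default 0.05). At each cutoff the graph of gene pairs
with similarity ≥ cutoff is built and its maximal cliques (size ≥ 2)
enumerated with pivoting Bron–Kerbosch (networkx), in canonical order
(larger first, then lexicographic) for determinism. A clique becomes a new
term unless it duplicates an existing term's gene set, or its Jaccard
overlap with a term already accepted *at the same cutoff* is ≥ `beta`
(default 0.5), in which case it is absorbed into that earlier, larger term.
Restricting overlap-merging to same-cutoff candidates keeps a coarse module
from swallowing its own sub-modules found at tighter cutoffs; and because
every term remains a maximal clique of its creation-cutoff graph, a term
created at a lower cutoff can never be a subset of an earlier term — which
guarantees the DAG invariant that creation cutoffs are non-increasing from
leaves toward the root. (An earlier union-merge variant violated exactly
this invariant on noisy matrices.) The sweep ends with a root term of all
genes, since the cutoff-0 graph is complete.

To score the DAG on the same 10-threshold axis as HAC, threshold h keeps the
terms created at cutoff ≥ 1 − h and reports the containment-maximal ones as
clusters (overlap allowed); uncovered genes are singletons. This bridge
reduces to the HAC semantics — fine modules at small h, the all-gene root at
h = 1 — and is a package design decision, not a property inherited from any
published mapping. The clique enumeration carries a configurable gene budget
(default 200) because the evaluation operates at planted-fixture scale.

## Incompleteness: estimation and simulation

Per-gene missing-annotation counts are estimated as
max(0, |complete| − |actual ortholog|), bounded to 0 ≤ n < 70; genes without
a usable ortholog mapping are excluded with a log message. The removal
simulation walks the distinct counts n from largest to smallest: at each n
it uniformly selects g_n not-yet-modified genes with ≥ n annotations,
uniformly deletes n annotations from each, and marks them modified — each
gene is touched at most once, and on feasible inputs the multiset of
per-gene removal counts equals the input distribution exactly.

When fewer than g_n genes are eligible (possible on synthetic fixtures,
where the distribution was not measured on the same genes), all eligible
genes are used and the shortfall carries to the next smaller n, with a
warning — this preserves total removal mass as closely as possible. Genes
reduced to zero annotations are retained with an empty set rather than
deleted. Replicates use per-replicate seeds master + index, so a collection
is reproducible from one integer and any single replicate can be re-derived.

## Evaluation

**Accuracy.** For each ground-truth class of 5–50 genes, a ROC point is
computed at each of the 10 clustering thresholds: the *representative
cluster* is the one containing the most class members (ties to the smaller
cluster, then lexicographic — when a class is split across clusters there
is no canonical cluster to score, so this deterministic maximal-TPR rule is
a package decision); TPR is the captured class fraction
and FPR the non-class genes the cluster drags in over all non-class genes.
If no cluster contains a class member the point is (0, 0). The AUC is the
trapezoid over the FPR-sorted points anchored at (0, 0) and (1, 1) — ten
operating points alone do not bound a curve. Under this anchoring both
degenerate clusterings (everything in one cluster; everything a singleton)
score exactly 0.5, and a clustering whose classes co-cluster exclusively at
every threshold scores exactly 1. For overlapping DAG clusters a gene may
count toward several classes' representative clusters simultaneously.

**Consistency** is CV(%) = 100·sd/mean of per-replicate AUCs per
(class, measure, method), with the sample (n−1) standard deviation, since
replicates sample the simulation process.

**Robustness** uses the reciprocal best match: each incomplete cluster
matches the complete cluster(s) of maximal positive overlap; a complete
cluster matched by several keeps the largest-overlap one (ties to the
smaller incomplete cluster, then lexicographic). The clustered fraction
averages, over complete clusters, the share of their genes found in the
best-matched cluster, counting matchless clusters as 0 — dissolution is
penalized, not dropped. The singleton fraction is the share of complete-set
singletons still singletons. Either fraction is undefined (reported as
missing) when its denominator is empty.

**Combination comparison** is the one-sided paired t-test over per-class
AUC vectors against the best-ranked combination, flagged at P < 0.05. With
zero variance of differences the test degenerates and the flag follows the
sign of the mean difference.

## Synthetic study fixtures

The generator plants known structure so every stage is testable without
downloads. The ontology is a rooted DAG whose level-1 terms head disjoint
class subtrees (each internal term has `branching` is_a children down to the
configured depth); terms at level ≥ 2 gain a second, part_of parent with
probability `multi_parent_prob` (default 0.2), drawn from a strictly
shallower level to preserve acyclicity. Each gene belongs to a home class
and draws its annotations from the home subtree with probability
`class_coherence` (default 0.9), else uniformly from all non-root terms;
the result is redundancy-reduced. The planted classes are the ground truth
for per-class ROC — the accuracy criterion is precisely "how well do genes
of the same class cluster together".

Missing counts follow a geometric distribution truncated to 0..69 — the
simplest monotone, long-tailed family consistent with the observed shape of
missing-annotation histograms — with two named regimes:

* **cellular-like** — 1–8 annotations drawn per gene, truncation parameter
  0.5 (mean ≈ 1 missing), depth-4 binary subtrees (7 terms/class);
* **multicellular-like** — 5–25 annotations per gene, parameter 0.13
  (mean ≈ 6.7 missing), depth-5 branching-3 subtrees (40 terms/class,
  27 leaves). The wider subtree is essential: annotation draws collapse to
  at most the subtree's leaf count after redundancy reduction, and the
  heavy-loss regime is only meaningful when effective annotation capacity
  is commensurate with the losses, mirroring the richer multicellular
  branch of the real ontology.

Default analysis sizes are 24 genes / 4 classes (cellular) and 32 genes /
4 classes (multicellular), with 10 thresholds and 20 replicates in the
numbered analysis scripts — small enough that the full 28-combination
factorial over all replicates runs in seconds while every class stays
inside the 5–50 evaluation window.

What the generator does **not** emulate: real GO term semantics, the exact
empirical annotation-count and missing-count histograms, inter-class
overlap of real biological processes (planted subtrees are disjoint apart
from multi-parent cross-links), and annotation bias (removal is uniform by
construction, matching the simulation procedure being modeled — the
evaluation isolates incompleteness *without* bias). Passing tests therefore
demonstrate the machinery's correctness and the direction of
incompleteness effects, not the numeric AUC/CV levels of any real corpus.

## Known limitations

* The clique-DAG method is a faithful-in-spirit reimplementation of
  threshold-sweep clique extraction, not a bit-compatible port of the
  original CliXO C++ tool; tie-breaking and the term-merge rule differ.
* On heavily degraded replicates the removal distribution can be infeasible
  for the surviving annotation counts; the carry-down fallback then removes
  less than the target mass (logged), so realized removal means can sit
  below the target.
* AVG combinations are the most robust to incompleteness precisely because
  of their dilution, so pooled complete+incomplete rankings can place
  individual AVG combinations above weak MAX/BMA ones even though the AVG
  group median stays below the MAX/BMA group median.
* Cross-namespace similarity, regulates-type relations and OWL inputs are
  out of scope.
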