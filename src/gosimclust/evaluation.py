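"""Scoring clustering accuracy, consistency and robustness.

Accuracy: for each ground-truth gene class of meaningful size (5-50
genes), a ROC curve over the 10 clustering thresholds — at each
threshold the representative cluster is the one containing the most
class members, TPR is the fraction of the class it captures and FPR the
fraction of non-class genes it drags in — and its trapezoidal AUC with
(0,0)/(1,1) anchors.  A perfect clustering scores 1; the degenerate
all-in-one and all-singletons clusterings both score 0.5.

Consistency: the coefficient of variation of AUC across simulation
replicates.  Robustness: reciprocal best-match overlap between the
complete-data clusters and each incomplete replicate's clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSet

CLASS_SIZE_MIN = 5
CLASS_SIZE_MAX = 50


@dataclass
class RocCurve:
    """Per-class ROC over clustering thresholds, with anchored AUC."""

    class_id: str
    points: list[tuple[float, float]]  # (FPR, TPR) per threshold
    auc: float


def _representative_cluster(class_genes: frozenset[str],
                            cs: ClusterSet) -> frozenset[str] | None:
    """The cluster containing the most class genes.

    Ties break to the smaller cluster, then lexicographically; if no
    cluster contains any class gene there is no representative.
    """
    best: frozenset[str] | None = None
    best_key: tuple | None = None
    for cluster in cs.clusters:
        overlap = len(cluster & class_genes)
        if overlap == 0:
            continue
        key = (-overlap, len(cluster), sorted(cluster))
        if best_key is None or key < best_key:
            best, best_key = cluster, key
    return best


def class_roc(class_genes: frozenset[str] | set[str],
              clusterings: list[ClusterSet],
              all_genes: frozenset[str] | set[str]) -> RocCurve:
    """ROC/AUC for one gene class across a list of threshold clusterings."""
    class_genes = frozenset(class_genes)
    all_genes = frozenset(all_genes)
    if not class_genes <= all_genes:
        raise ValueError("class genes must be a subset of the gene universe")
    if not CLASS_SIZE_MIN <= len(class_genes) <= CLASS_SIZE_MAX:
        raise ValueError(
            f"class size {len(class_genes)} outside [{CLASS_SIZE_MIN}, {CLASS_SIZE_MAX}]")
    negatives = len(all_genes - class_genes)
    points = []
    for cs in clusterings:
        rep = _representative_cluster(class_genes, cs)
        if rep is None:
            points.append((0.0, 0.0))
            continue
        tpr = len(rep & class_genes) / len(class_genes)
        fpr = len(rep - class_genes) / negatives if negatives else 0.0
        points.append((fpr, tpr))
    anchored = sorted(points + [(0.0, 0.0), (1.0, 1.0)])
    xs = [p[0] for p in anchored]
    ys = [p[1] for p in anchored]
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(class_id="", points=points, auc=auc)


def auc_table(classes: dict[str, frozenset[str]],
              results: dict[tuple[str, str, str], list[ClusterSet]],
              all_genes: frozenset[str] | set[str]) -> pd.DataFrame:
    """Tidy AUC table: one row per (class, measure spec, method, replicate).

    ``results`` maps (spec name, method, replicate id) to the threshold
    clusterings of that run; replicate id "complete" denotes the
    unperturbed set.
    """
    rows = []
    for (spec_name, method, replicate), clusterings in sorted(results.items()):
        for class_id, genes in sorted(classes.items()):
            roc = class_roc(genes, clusterings, all_genes)
            rows.append({"class": class_id, "spec": spec_name, "method": method,
                         "replicate": replicate, "auc": roc.auc})
    return pd.DataFrame(rows, columns=["class", "spec", "method", "replicate", "auc"])


def cv_of_auc(aucs: list[float]) -> float | None:
    """CV(%) = 100 * sample sd / mean of per-replicate AUC values.

    Returns None when the mean is zero (undefined).
    """
    if len(aucs) < 2:
        raise ValueError("need at least two replicates")
    arr = np.asarray(aucs, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class MatchMap:
    """Reciprocal best matches: complete cluster index -> incomplete index."""

    best: dict[int, int]  # complete idx -> incomplete idx
    overlaps: dict[tuple[int, int], int]


def best_match(complete: ClusterSet, incomplete: ClusterSet) -> MatchMap:
    """Two-step reciprocal best-match between two cluster collections.

    Step 1: each incomplete cluster is matched to the complete
    cluster(s) sharing the largest (positive) number of genes.  Step 2:
    a complete cluster matched by several incomplete clusters keeps the
    one with the largest overlap, ties going to the smaller incomplete
    cluster and then the lexicographically first.
    """
    candidates: dict[int, list[int]] = {i: [] for i in range(len(complete.clusters))}
    overlaps: dict[tuple[int, int], int] = {}
    for j, inc in enumerate(incomplete.clusters):
        best_overlap = 0
        matched: list[int] = []
        for i, comp in enumerate(complete.clusters):
            ov = len(comp & inc)
            overlaps[(i, j)] = ov
            if ov > best_overlap:
                best_overlap, matched = ov, [i]
            elif ov == best_overlap and ov > 0:
                matched.append(i)
        for i in matched:
            candidates[i].append(j)
    best: dict[int, int] = {}
    for i, js in candidates.items():
        if not js:
            continue
        best[i] = min(js, key=lambda j: (-overlaps[(i, j)],
                                         len(incomplete.clusters[j]),
                                         sorted(incomplete.clusters[j])))
    return MatchMap(best=best, overlaps=overlaps)


def robustness(complete: ClusterSet, incomplete: ClusterSet,
               match: MatchMap) -> tuple[float | None, float | None]:
    """(clustered fraction, singleton fraction) at one threshold.

    Clustered fraction: mean over complete clusters of the share of
    their genes found in the best-matched incomplete cluster, counting
    matchless clusters as 0 — dissolving a cluster is penalized, not
    ignored.  Singleton fraction: the share of complete-set singletons
    that are still singletons.  Either is None when its denominator is
    empty.
    """
    if complete.clusters:
        fracs = []
        for i, comp in enumerate(complete.clusters):
            j = match.best.get(i)
            if j is None:
                fracs.append(0.0)
            else:
                fracs.append(len(comp & incomplete.clusters[j]) / len(comp))
        clustered = float(np.mean(fracs))
    else:
        clustered = None
    if complete.singletons:
        single = len(complete.singletons & incomplete.singletons) / len(complete.singletons)
    else:
        single = None
    return clustered, single


def compare_combinations(auc_a: list[float], auc_b: list[float],
                         alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sided paired t-test of 'combination A scores below combination B'.

    Returns (t statistic, p value, significant flag).  With zero
    variance of the paired differences the test degenerates; the flag is
    then set by the sign of the mean difference (p reported as 0 or 1).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if diffs.mean() < 0:
            return -math.inf, 0.0, True
        return (math.inf if diffs.mean() > 0 else 0.0), 1.0, False
    t, p = stats.ttest_rel(a, b, alternative="less")
    return float(t), float(p), bool(p < alpha)


def write_match_map(match: MatchMap, path: str) -> None:
    """TSV export: complete cluster ID, incomplete cluster ID, overlap."""
    with open(path, "w") as fh:
        fh.write("complete\tincomplete\toverlap\n")
        for i in sorted(match.best):
            j = match.best[i]
            fh.write(f"C{i}\tI{j}\t{match.overlaps[(i, j)]}\n")
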