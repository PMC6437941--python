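"""Compute the 14 gene-level similarity matrices on the complete cellular
fixture and cluster each with both methods.

For every measure the script reports the mean within-class vs
between-class similarity (the contrast clustering exploits) and writes
the Lin-BMA matrix plus its HAC and clique-DAG cluster sets as TSVs
under results/similarity/.

Run from the repository root:  python analysis/02_similarity_and_clustering.py
(expects results/fixtures/ from 01_generate_fixtures.py; regenerates it
in memory if absent)
"""

import os

import numpy as np

from gosimclust.annotations import compute_ic
from gosimclust.clustering import (clixo_cluster, cut_tree, dag_clusters_at_thresholds,
                                   default_thresholds, hac_cluster,
                                   write_cluster_sets, write_inferred_dag)
from gosimclust.similarity import (TermSimCache, all_measure_specs, gene_sim_matrix,
                                   write_sim_matrix)
from gosimclust.synthetic import cellular_config, generate_study_fixture

SEED = 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "similarity")


def main() -> None:
    fx = generate_study_fixture(cellular_config(n_genes=24, n_leaf_classes=4, seed=SEED))
    ann = fx.annotations
    ic = compute_ic(ann)
    cache = TermSimCache(ann, ic)
    gene_class = {g: cid for cid, gs in fx.classes.items() for g in gs}
    os.makedirs(OUT, exist_ok=True)

    print(f"{'measure':22s} {'within':>8s} {'between':>8s} {'contrast':>9s}")
    for spec in all_measure_specs():
        mat = gene_sim_matrix(ann, spec, ic, cache=cache)
        within, between = [], []
        for i, gx in enumerate(mat.genes):
            for gy in mat.genes[i + 1:]:
                (within if gene_class[gx] == gene_class[gy] else between).append(
                    mat.sim(gx, gy))
        w, b = np.mean(within), np.mean(between)
        print(f"{spec.name:22s} {w:8.3f} {b:8.3f} {w - b:9.3f}")
        if spec.name == "lin_BMA":
            write_sim_matrix(mat, os.path.join(OUT, "lin_BMA_matrix.tsv"))
            tree = hac_cluster(mat)
            write_cluster_sets(cut_tree(tree, default_thresholds()),
                               os.path.join(OUT, "lin_BMA_hac_clusters.tsv"))
            inferred = clixo_cluster(mat)
            write_inferred_dag(inferred, os.path.join(OUT, "lin_BMA_inferred_dag.tsv"))
            write_cluster_sets(dag_clusters_at_thresholds(inferred, default_thresholds()),
                               os.path.join(OUT, "lin_BMA_dag_clusters.tsv"))
    print(f"Lin-BMA matrix, HAC cuts and inferred DAG written under {os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
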