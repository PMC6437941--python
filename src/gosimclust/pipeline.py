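"""End-to-end experiment driver: the full factorial of 14 gene-level
measures x 2 clustering methods, on the complete annotation set and on
simulated incomplete replicates, scored for accuracy (per-class AUC),
consistency (CV of AUC) and robustness (reciprocal best-match overlap).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .annotations import AnnotationSet, compute_ic, remove_redundant
from .clustering import (ClusterSet, clixo_cluster, cut_tree,
                         dag_clusters_at_thresholds, default_thresholds,
                         hac_cluster)
from .evaluation import auc_table, best_match, compare_combinations, cv_of_auc, robustness
from .incompleteness import simulate_collection
from .similarity import MeasureSpec, TermSimCache, all_measure_specs, gene_sim_matrix
from .synthetic import SyntheticConfig, StudyFixture, generate_study_fixture

logger = logging.getLogger(__name__)

METHODS = ("hac", "dag")


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    spec_names: list[str] = field(default_factory=lambda: [s.name for s in all_measure_specs()])
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    linkage: str = "average"
    clixo_alpha: float = 0.05
    clixo_beta: float = 0.5
    replicates: int = 5
    n_thresholds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_thresholds < 2:
            raise ValueError("need at least 2 thresholds")
        valid = {s.name for s in all_measure_specs()}
        bad = set(self.spec_names) - valid
        if bad:
            raise ValueError(f"unknown measure specs: {sorted(bad)}")
        bad_methods = set(self.methods) - set(METHODS)
        if bad_methods:
            raise ValueError(f"unknown clustering methods: {sorted(bad_methods)}")


def cluster_annotation_set(ann: AnnotationSet, cfg: RunConfig
                           ) -> dict[tuple[str, str], list[ClusterSet]]:
    """All (spec, method) threshold clusterings for one annotation set.

    IC is recomputed from the set itself, as a similarity tool pointed at
    this corpus would; the term-similarity cache is shared across the
    four IC-based measures.
    """
    ic = compute_ic(ann)
    cache = TermSimCache(ann, ic)
    thresholds = default_thresholds(cfg.n_thresholds)
    out: dict[tuple[str, str], list[ClusterSet]] = {}
    for name in cfg.spec_names:
        spec = MeasureSpec.from_name(name)
        sim = gene_sim_matrix(ann, spec, ic, cache=cache)
        if "hac" in cfg.methods:
            tree = hac_cluster(sim, linkage=cfg.linkage)
            out[(name, "hac")] = cut_tree(tree, thresholds)
        if "dag" in cfg.methods:
            inferred = clixo_cluster(sim, alpha=cfg.clixo_alpha, beta=cfg.clixo_beta)
            out[(name, "dag")] = dag_clusters_at_thresholds(inferred, thresholds)
    return out


@dataclass
class ExperimentReport:
    """All tables of one run, plus the manifest describing it."""

    auc: pd.DataFrame          # class, spec, method, replicate, auc
    cv: pd.DataFrame           # class, spec, method, cv_percent
    robustness: pd.DataFrame   # spec, method, replicate, threshold, fractions
    ranking: pd.DataFrame      # spec, method, median auc, significance vs best
    manifest: dict


def run_experiment(cfg: RunConfig, fixture: StudyFixture | None = None) -> ExperimentReport:
    """Run the whole pipeline on a synthetic (or supplied) study fixture."""
    if fixture is None:
        fixture = generate_study_fixture(
            dataclasses.replace(cfg.synthetic, seed=cfg.seed))
    complete = remove_redundant(fixture.annotations)
    logger.info("run_experiment: %d genes, %d classes, %d specs, %d replicates",
                len(complete), len(fixture.classes), len(cfg.spec_names), cfg.replicates)

    results: dict[tuple[str, str, str], list[ClusterSet]] = {}
    for (name, method), clusterings in cluster_annotation_set(complete, cfg).items():
        results[(name, method, "complete")] = clusterings

    collection = simulate_collection(complete, fixture.missing_dist,
                                     reps=cfg.replicates, seed=cfg.seed + 1)
    for r, replicate in enumerate(collection.replicates):
        for (name, method), clusterings in cluster_annotation_set(replicate, cfg).items():
            results[(name, method, f"rep{r:03d}")] = clusterings

    all_genes = frozenset(complete.annotated_genes())
    auc = auc_table(fixture.classes, results, all_genes)

    cv_rows = []
    incompl = auc[auc.replicate != "complete"]
    for (cls, spec, method), grp in incompl.groupby(["class", "spec", "method"]):
        if len(grp) >= 2:
            cv_rows.append({"class": cls, "spec": spec, "method": method,
                            "cv_percent": cv_of_auc(grp.auc.tolist())})
    cv = pd.DataFrame(cv_rows, columns=["class", "spec", "method", "cv_percent"])

    rob_rows = []
    for name in cfg.spec_names:
        for method in cfg.methods:
            comp = results[(name, method, "complete")]
            for r in range(cfg.replicates):
                inc = results[(name, method, f"rep{r:03d}")]
                for cs_c, cs_i in zip(comp, inc):
                    mm = best_match(cs_c, cs_i)
                    clustered, single = robustness(cs_c, cs_i, mm)
                    rob_rows.append({"spec": name, "method": method,
                                     "replicate": f"rep{r:03d}",
                                     "threshold": cs_c.threshold,
                                     "clustered_fraction": clustered,
                                     "singleton_fraction": single})
    rob = pd.DataFrame(rob_rows, columns=["spec", "method", "replicate", "threshold",
                                          "clustered_fraction", "singleton_fraction"])

    ranking = summarize_ranking(auc)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "n_genes": len(complete),
        "n_classes": len(fixture.classes),
        "combinations": len(cfg.spec_names) * len(cfg.methods),
        "replicates_completed": cfg.replicates,
    }
    return ExperimentReport(auc=auc, cv=cv, robustness=rob, ranking=ranking,
                            manifest=manifest)


def summarize_ranking(auc: pd.DataFrame, replicate: str | None = None) -> pd.DataFrame:
    """Order combinations by median AUC and flag those significantly below
    the best one (one-sided paired t-test over per-class mean AUC, P < 0.05).
    """
    df = auc if replicate is None else auc[auc.replicate == replicate]
    per_class = (df.groupby(["spec", "method", "class"], as_index=False)
                 .auc.mean())
    medians = (per_class.groupby(["spec", "method"])
               .auc.median().sort_values(ascending=False))
    if medians.empty:
        raise ValueError("no AUC rows to summarize")
    best_spec, best_method = medians.index[0]
    best_vec = (per_class[(per_class.spec == best_spec) & (per_class.method == best_method)]
                .set_index("class").auc)
    rows = []
    for (spec, method), med in medians.items():
        vec = (per_class[(per_class.spec == spec) & (per_class.method == method)]
               .set_index("class").auc)
        common = sorted(set(vec.index) & set(best_vec.index))
        if (spec, method) == (best_spec, best_method) or len(common) < 3:
            sig, p = False, None
        else:
            _, p, sig = compare_combinations(vec.loc[common].tolist(),
                                             best_vec.loc[common].tolist())
        rows.append({"spec": spec, "method": method, "median_auc": med,
                     "p_vs_best": p, "below_best": sig})
    return pd.DataFrame(rows, columns=["spec", "method", "median_auc",
                                       "p_vs_best", "below_best"])


def write_report(report: ExperimentReport, outdir: str) -> None:
    """Write all tables and the manifest to a directory."""
    os.makedirs(outdir, exist_ok=True)
    report.auc.to_csv(os.path.join(outdir, "auc.tsv"), sep="\t", index=False)
    report.cv.to_csv(os.path.join(outdir, "cv.tsv"), sep="\t", index=False)
    report.robustness.to_csv(os.path.join(outdir, "robustness.tsv"), sep="\t", index=False)
    report.ranking.to_csv(os.path.join(outdir, "ranking.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["synthetic"] = dataclasses.asdict(cfg.synthetic)
    return d
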