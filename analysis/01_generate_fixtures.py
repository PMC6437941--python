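"""Generate the two synthetic study fixtures and summarize their
incompleteness regimes.

Creates a cellular-process-like corpus (few annotations per gene, mild
annotation loss) and a multicellular-process-like corpus (rich
annotation sets, heavy loss), mirroring the contrast between the
well-studied yeast-backed and mouse-backed halves of the analysis.
Writes each fixture in the interchange formats (OBO ontology,
annotation/class/missing-distribution TSVs) under results/fixtures/.

Run from the repository root:  python analysis/01_generate_fixtures.py
"""

import os

from gosimclust.ontology import write_obo
from gosimclust.synthetic import (cellular_config, generate_study_fixture,
                                  multicellular_config, write_annotations_tsv,
                                  write_classes)
from gosimclust.incompleteness import write_missing_dist

SEED = 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "fixtures")


def main() -> None:
    regimes = {
        "cellular": cellular_config(n_genes=24, n_leaf_classes=4, seed=SEED),
        "multicellular": multicellular_config(n_genes=32, n_leaf_classes=4, seed=SEED),
    }
    for name, cfg in regimes.items():
        fx = generate_study_fixture(cfg)
        outdir = os.path.join(OUT, name)
        os.makedirs(outdir, exist_ok=True)
        write_obo(fx.ontology, os.path.join(outdir, "ontology.obo"))
        write_annotations_tsv(fx.annotations, os.path.join(outdir, "annotations.tsv"))
        write_classes(fx.classes, os.path.join(outdir, "classes.tsv"))
        write_missing_dist(fx.missing_dist, os.path.join(outdir, "missing_dist.tsv"))
        sizes = [len(ts) for ts in fx.annotations.annotations.values()]
        print(f"{name}: {len(fx.annotations)} genes in {len(fx.classes)} classes, "
              f"{len(fx.ontology.terms)} ontology terms; "
              f"annotations/gene {min(sizes)}-{max(sizes)} "
              f"(mean {sum(sizes)/len(sizes):.1f}); "
              f"missing-count mean {fx.missing_dist.mean():.2f}, "
              f"max {max(fx.missing_dist.g)}")
    print(f"fixtures written under {os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
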