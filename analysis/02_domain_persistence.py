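#!/usr/bin/env python
"""Persistence-based domain-core comparison of aerobic vs anaerobic genomes.

Reads the annotation and label tables written by 01_simulate.py (exercising
the full ingest path), builds the architecture matrix, computes per-group
persistence, derives the 95%-threshold core split and the <= 1% low-
persistence split, and writes the lists plus PCA coordinates and a Newick
dendrogram under results/.
"""

from pathlib import Path

from anaerodesign import persistence, synthetic
from anaerodesign.domains import matrix_from_hits, parse_domain_annotations
from anaerodesign.reference import EPSILON_RARE, TAU_CORE_LONG

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    with open(IN / "domain_annotations.tsv") as fh:
        hits = parse_domain_annotations(fh)
    labels = synthetic.read_labels(str(IN / "strain_labels.tsv"))
    matrix = matrix_from_hits(hits, labels)
    pt = persistence.persistence_table(matrix, labels)

    split_core = persistence.split_cores(
        persistence.core_at_threshold(pt["aerobic"], TAU_CORE_LONG),
        persistence.core_at_threshold(pt["anaerobic"], TAU_CORE_LONG),
        thresholds=(TAU_CORE_LONG,),
    )
    split_rare = persistence.specific_by_low_persistence(
        pt["aerobic"], pt["anaerobic"], epsilon=EPSILON_RARE, tau_presence=TAU_CORE_LONG
    )
    lists = persistence.export_lists(pt, {"core95": split_core, "rare1pct": split_rare})
    lists.to_csv(OUT / "persistence_lists.tsv", sep="\t", float_format="%.6g")
    print(
        f"95% core split: {len(split_core.shared)} shared, "
        f"{len(split_core.aerobe_specific)} aerobe-specific, "
        f"{len(split_core.anaerobe_specific)} anaerobe-specific"
    )
    print(
        f"<=1% low-persistence split: {len(split_rare.anaerobe_specific)} "
        f"anaerobe-specific"
    )

    pca = persistence.run_pca(matrix.binary)
    pca.scores.iloc[:, :2].to_csv(OUT / "pca_scores.tsv", sep="\t", float_format="%.6g")
    print(
        "PCA variance fractions (PC1, PC2): "
        f"{pca.variance_fractions[0]:.3f}, {pca.variance_fractions[1]:.3f}"
    )

    dend = persistence.hierarchical_tree(matrix.binary)
    (OUT / "dendrogram.nwk").write_text(dend.to_newick())
    focal = labels["strain_id"].iloc[0]
    branch = persistence.extract_branch(dend, focal, depth=1)
    print(f"first split: branch containing {focal} holds {len(branch)} strains")


if __name__ == "__main__":
    main()
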