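#!/usr/bin/env python
"""Consistency filtering of condition-wise fold changes vs anaerobic growth.

Reads the counts and condition map written by 01_simulate.py, normalizes
(median of ratios), computes the 13 pairwise log2 fold changes against the
anaerobic reference, imputes non-finite cells to 0 / +-4 by fdr, applies the
7-of-13 direction-consistency + 3x strong-fold rule, and writes the imputed
matrix and the selected gene list under results/.
"""

from pathlib import Path

from anaerodesign import synthetic, transcriptome as tx

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    cm = synthetic.read_counts(
        str(IN / "counts.tsv"), str(IN / "condition_map.tsv"), reference="anaerobic"
    )
    rule = tx.ConsistencyRule()
    fc = tx.log2fc_matrix(cm, rule)
    fc.log2fc.to_csv(OUT / "log2fc_imputed.tsv", sep="\t", float_format="%.6g")
    selected = tx.consistency_filter(fc, rule)
    selected.to_csv(OUT / "selected_genes.tsv", sep="\t")

    n_imp = int(fc.imputed.to_numpy().sum())
    n_up = int((selected["direction"] == "up").sum())
    n_down = int((selected["direction"] == "down").sum())
    print(
        f"{len(fc.comparisons)} comparisons vs {cm.reference}; "
        f"{n_imp} cells imputed to 0/+-4"
    )
    print(
        f"consistency rule (>= {rule.min_consistent} same-direction, "
        f">= {rule.min_strong} at >= {rule.strong_fold:g}-fold): "
        f"{len(selected)} genes selected ({n_up} up, {n_down} down under anoxia)"
    )


if __name__ == "__main__":
    main()
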