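#!/usr/bin/env python
"""Generate the synthetic study inputs and write them in the exchange formats.

Emits, under results/inputs/: the strain lifestyle label table, the per-strain
domain annotation table, gene coordinates, the transcriptome count matrix with
its condition map, and the toy metabolic model as a tabular reaction file.
Downstream drivers re-read these files (or regenerate them by seed — the
generators are deterministic, so both routes agree).
"""

from pathlib import Path

from anaerodesign import fba, synthetic

SEED = 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    gcfg = synthetic.SyntheticGenomeConfig(seed=SEED)
    labels, matrix, coords, truth = synthetic.generate_domain_dataset(gcfg)
    (OUT / "strain_labels.tsv").write_text(synthetic.write_labels(labels))
    (OUT / "domain_annotations.tsv").write_text(synthetic.domain_hits_table(gcfg))
    coords.to_csv(OUT / "gene_coordinates.tsv", sep="\t", index=False)
    n_ana = len(truth.architectures_of(synthetic.ANAEROBE_SPECIFIC))
    print(
        f"genomes: {gcfg.n_aerobic} aerobic + {gcfg.n_anaerobic} facultative "
        f"anaerobic; {matrix.counts.shape[1]} architectures "
        f"({n_ana} planted anaerobe-specific)"
    )

    tcfg = synthetic.SyntheticTranscriptomeConfig(seed=SEED)
    cm, de_truth = synthetic.generate_transcriptome(tcfg)
    counts_tsv, cond_tsv = synthetic.write_counts(cm)
    (OUT / "counts.tsv").write_text(counts_tsv)
    (OUT / "condition_map.tsv").write_text(cond_tsv)
    print(
        f"transcriptome: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples "
        f"over {len(cm.conditions)} conditions (reference: {cm.reference}); "
        f"planted {len(de_truth.genes_of('up'))} up / {len(de_truth.genes_of('down'))} down"
    )

    model = synthetic.generate_toy_model()
    (OUT / "toy_model.tsv").write_text(fba.write_model(model))
    print(f"toy metabolic model: {len(model.reactions)} reactions written")


if __name__ == "__main__":
    main()
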