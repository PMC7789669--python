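"""Desk-scale evaluation experiments for the pipeline's core claims.

Each function generates its inputs with the synthetic module under a caller
seed, runs the corresponding pipeline stage, and measures recovery of the
planted ground truth (or, for the toy metabolic model, the qualitative
growth/gap behaviour). The problem sizes are the package's standard
evaluation conditions; docs/methods.md discusses how they relate to the
cluster-scale setting recorded in :mod:`anaerodesign.reference`.
"""

from __future__ import annotations

import numpy as np

from . import design, fba, persistence, reference, rf, synthetic, transcriptome


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def pdc_recovery(seed: int = 1) -> dict:
    """Planted-architecture recovery of the 95%-threshold specific list.

    Conditions: 200 aerobic + 200 anaerobic genomes, dropout 0.02,
    cross-group contamination 0.005 (the generator defaults).
    """
    cfg = synthetic.SyntheticGenomeConfig(seed=_child_seed(seed, 0))
    labels, matrix, _, truth = synthetic.generate_domain_dataset(cfg)
    pt = persistence.persistence_table(matrix, labels)
    split = persistence.split_cores(
        persistence.core_at_threshold(pt["aerobic"], reference.TAU_CORE_LONG),
        persistence.core_at_threshold(pt["anaerobic"], reference.TAU_CORE_LONG),
    )
    planted = truth.architectures_of(synthetic.ANAEROBE_SPECIFIC)
    found = split.anaerobe_specific
    recovery = len(found & planted) / len(planted)
    false_discovery = len(found - planted) / max(len(found), 1)
    return {
        "recovery_pct": 100.0 * recovery,
        "false_discovery_pct": 100.0 * false_discovery,
        "n_strains": cfg.n_aerobic + cfg.n_anaerobic,
    }


def rf_top10_rate(seed: int = 1, n_seeds: int = 20) -> dict:
    """Fraction of seeds in which all planted discriminators rank top-10.

    Conditions per seed: 150+150 genomes, 5 planted anaerobe-specific
    architectures among 500 accessory ones, dropout 0.02; protocol scaled to
    10 repetitions x 100 trees on balanced 100-genome class subsamples.
    """
    hits = 0
    for k in range(n_seeds):
        s = _child_seed(seed, 100 + k)
        cfg = synthetic.SyntheticGenomeConfig(
            n_aerobic=150, n_anaerobic=150, n_shared_core=0, n_aerobe_specific=0,
            n_anaerobe_specific=5, n_accessory=500, dropout_rate=0.02,
            contamination_rate=0.0, seed=s,
        )
        labels, matrix, _, truth = synthetic.generate_domain_dataset(cfg)
        protocol = rf.RFProtocolConfig(
            n_per_class=100, repetitions=10, trees_per_model=100, seed=s
        )
        table = rf.run_protocol(matrix, labels, protocol)
        planted = truth.architectures_of(synthetic.ANAEROBE_SPECIFIC)
        if planted <= set(table.index[:10]):
            hits += 1
    return {"top10_pct": 100.0 * hits / n_seeds, "n_seeds": n_seeds}


def transcriptome_recovery(seed: int = 1) -> dict:
    """Sensitivity/precision of the consistency filter on planted genes.

    Conditions: 2000 genes over 14 conditions (47 samples), planted 8-fold
    regulation in 60 up + 60 down genes, 30 weak decoys, NB dispersion 0.05.
    """
    cfg = synthetic.SyntheticTranscriptomeConfig(seed=_child_seed(seed, 200))
    cm, truth = synthetic.generate_transcriptome(cfg)
    fc = transcriptome.log2fc_matrix(cm)
    selected = set(transcriptome.consistency_filter(fc).index)
    planted = truth.genes_of("up") | truth.genes_of("down")
    tp = len(selected & planted)
    return {
        "sensitivity_pct": 100.0 * tp / len(planted),
        "precision_pct": 100.0 * tp / max(len(selected), 1),
        "n_genes": cfg.n_genes,
    }


def transcriptome_null(seed: int = 1, n_seeds: int = 20, n_genes: int = 300) -> dict:
    """Mean selected-set size with no planted regulation (null control)."""
    sizes = []
    for k in range(n_seeds):
        cfg = synthetic.SyntheticTranscriptomeConfig(
            n_genes=n_genes, n_planted_up=0, n_planted_down=0, n_planted_weak=0,
            seed=_child_seed(seed, 300 + k),
        )
        cm, _ = synthetic.generate_transcriptome(cfg)
        fc = transcriptome.log2fc_matrix(cm)
        sizes.append(len(transcriptome.consistency_filter(fc)))
    rule = transcriptome.ConsistencyRule()
    return {
        "mean_selected": float(np.mean(sizes)),
        "alpha_times_n": rule.alpha * n_genes,
        "n_seeds": n_seeds,
    }


def toy_model_report() -> dict:
    """Growth and gap behaviour of the toy model under the standard media."""
    model = synthetic.generate_toy_model()
    medium = synthetic.toy_medium()
    anoxic = fba.set_anoxic(medium)
    denit = frozenset(synthetic.DENITRIFICATION_REACTIONS)
    vitamins = {ex: fba.OPEN_UPTAKE for ex in synthetic.VITAMIN_EXCHANGES}
    from dataclasses import replace

    supplemented = replace(anoxic, uptakes={**anoxic.uptakes, **vitamins})
    blocked = fba.blocked_biomass_precursors(model, anoxic, enabled=denit)
    minimal = fba.propose_media_supplements(
        model, anoxic, synthetic.VITAMIN_EXCHANGES, enabled=denit
    )
    return {
        "aerobic_growth": fba.fba(model, medium).growth,
        "anoxic_growth": fba.fba(model, anoxic).growth,
        "anoxic_denitrifying_growth": fba.fba(model, anoxic, enabled=denit).growth,
        "anoxic_supplemented_growth": fba.fba(model, supplemented, enabled=denit).growth,
        "blocked_precursors": sorted(blocked.index[blocked["blocked"]]),
        "minimal_supplement_sets": [sorted(s) for s in minimal],
        "n_reactions": len(model.reactions),
    }


def design_report() -> dict:
    """Totals of the packaged categorized design table."""
    summary = design.summarize_design(design.load_design_reference())
    return {
        "known_function_genes": summary.known_gene_total,
        "unknown_function_domains": summary.unknown_entry_total,
        "total_genes": summary.grand_total,
        "vitamins": len(summary.supplements),
        "n_entries": len(summary.table),
    }


def arithmetic_report(seed: int = 1) -> dict:
    """List-arithmetic quantities recomputed from package inputs."""
    cfg = synthetic.SyntheticTranscriptomeConfig(
        n_genes=50, n_planted_up=0, n_planted_down=0, n_planted_weak=0,
        seed=_child_seed(seed, 400),
    )
    cm, _ = synthetic.generate_transcriptome(cfg)
    n_comparisons = len(cm.conditions) - 1
    gini = reference.synthetic_reference_gini(seed=_child_seed(seed, 401))
    high = rf.select_by_gini(gini, reference.GINI_THRESHOLD_HIGH)
    return {
        "total_strains": reference.total_strains(),
        "restricted_branch_strains": reference.restricted_branch_size(),
        "pairwise_comparisons": n_comparisons,
        "rf_input_domains": len(gini),
        "high_gini_domains": len(high),
    }
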