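"""Evidence integration into a categorized strain-design table.

Candidates from the three in-silico methods — protein-domain comparisons
(PDC), transcriptome consistency filtering (T) and metabolic-model gap
analysis (GSM) — are merged into one evidence table carrying source tags,
cumulative-Gini weights, persistence values and a functional category.
Domains of unknown function (DUFs) are retained only when their genes
co-localise with retained known-function genes; the final summary reports
per-category gene and domain counts plus the vitamin supplements that
replace oxygen-dependent cofactor biosynthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ConfigError
from .persistence import CoreSplit

KNOWN_CATEGORIES = (
    "nitrogen metabolism",
    "hydrogenases",
    "cytochrome C",
    "pyrimidine & amino acid biosynthesis",
    "ATP generation",
)
UNKNOWN_CATEGORY = "unknown function"
EXCLUDED_CATEGORY = "excluded"
CATEGORIES = KNOWN_CATEGORIES + (UNKNOWN_CATEGORY, EXCLUDED_CATEGORY)

#: Medium additions that substitute for oxygen-dependent cofactor biosynthesis.
REFERENCE_VITAMINS = ("vitamin B12", "vitamin B6", "vitamin K2")


def load_design_reference() -> pd.DataFrame:
    """Packaged categorized design table (gene, category, domains, sources)."""
    with resources.files("anaerodesign.data").joinpath("design_reference.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t").set_index("gene")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ConfigError(f"design reference contains unknown categories: {sorted(bad)}")
    return table


def merge_evidence(
    pdc: CoreSplit,
    gini: pd.DataFrame | None,
    transcriptome: Iterable[str],
    gsm: Iterable[str],
    category_map: Mapping[str, str],
    persistence_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Union of all method candidates with source tags and weights.

    Every entry carries at least one tag from {PDC, T, GSM}; cumulative-Gini
    weight is attached where available (0 otherwise); entries found in the
    aerobe-specific PDC list are categorized ``excluded``. Candidates without
    a category-map entry fall back to ``unknown function``.
    """
    transcriptome = frozenset(transcriptome)
    gsm = frozenset(gsm)
    pdc_all = pdc.anaerobe_specific | pdc.aerobe_specific
    candidates = sorted(pdc_all | transcriptome | gsm)
    rows = []
    for key in candidates:
        sources = []
        if key in pdc_all:
            sources.append("PDC")
        if key in transcriptome:
            sources.append("T")
        if key in gsm:
            sources.append("GSM")
        weight = 0.0
        if gini is not None and key in gini.index:
            weight = float(gini.loc[key, "cumulative_gini"])
        p_aer = p_ana = float("nan")
        if persistence_table is not None and key in persistence_table.index:
            p_aer = float(persistence_table.loc[key, "aerobic"])
            p_ana = float(persistence_table.loc[key, "anaerobic"])
        if key in pdc.aerobe_specific:
            specificity, category = "aerobe_specific", EXCLUDED_CATEGORY
        else:
            specificity = "anaerobe_specific" if key in pdc.anaerobe_specific else ""
            category = category_map.get(key, UNKNOWN_CATEGORY)
        rows.append(
            (
                key, ",".join(sources), weight, p_aer, p_ana, specificity,
                category, 1, category == UNKNOWN_CATEGORY,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate", "sources", "cumulative_gini", "persistence_aerobic",
            "persistence_anaerobic", "specificity", "category", "n_domains",
            "unknown_function",
        ],
    ).set_index("candidate")


def synthetic_category_map(keys: Iterable[str], gsm_genes: Mapping[str, str] | None = None) -> dict[str, str]:
    """Rule-driven category assignment for synthetic candidates.

    Keys containing "DUF" map to unknown function; known toy-model gene
    labels use ``gsm_genes``; remaining keys cycle deterministically (sorted
    order) over the known-function categories. Stands in for the manual
    literature curation of a real design round.
    """
    out: dict[str, str] = {}
    cycle = 0
    for key in sorted(set(keys)):
        if "DUF" in key:
            out[key] = UNKNOWN_CATEGORY
        elif gsm_genes and key in gsm_genes:
            out[key] = gsm_genes[key]
        else:
            out[key] = KNOWN_CATEGORIES[cycle % len(KNOWN_CATEGORIES)]
            cycle += 1
    return out


#: Functional categories of the toy-model gene labels (gap-analysis output).
TOY_GENE_CATEGORIES = {
    "narG": "nitrogen metabolism", "narH": "nitrogen metabolism",
    "narI": "nitrogen metabolism", "nirS": "nitrogen metabolism",
    "norB": "nitrogen metabolism", "norC": "nitrogen metabolism",
    "nosZ": "nitrogen metabolism", "narK1": "nitrogen metabolism",
    "narK2": "nitrogen metabolism",
    "cobG": "pyrimidine & amino acid biosynthesis",
    "cobNST": "pyrimidine & amino acid biosynthesis",
    "pdxH": "pyrimidine & amino acid biosynthesis",
    "menG": "pyrimidine & amino acid biosynthesis",
    "ubiE": "pyrimidine & amino acid biosynthesis",
    "btuB": "pyrimidine & amino acid biosynthesis",
    "cyoA": "ATP generation", "cyoB": "ATP generation",
}


def duf_colocalisation_filter(
    duf: Iterable[str],
    coords: pd.DataFrame,
    retained: Iterable[str],
    window: int = 5,
    min_fraction: float = 0.5,
) -> tuple[frozenset[str], frozenset[str]]:
    """Keep DUFs whose genes neighbour retained known-function genes.

    A DUF architecture is retained iff, in at least ``min_fraction`` of the
    genomes carrying it (``coords`` should already be restricted to the
    anaerobic strain set), its gene lies within ``window`` gene positions of
    a gene whose architecture is in ``retained``. Others are reported as
    unresolved. Strand-agnostic; a gene is never its own neighbour.
    """
    if window < 0:
        raise ConfigError(f"window must be >= 0, got {window}")
    if not 0 < min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    retained = frozenset(retained)
    kept: set[str] = set()
    unresolved: set[str] = set()
    by_strain = dict(tuple(coords.groupby("strain_id", sort=False)))
    for arch in sorted(set(duf)):
        carriers = 0
        colocal = 0
        for strain, sub in by_strain.items():
            duf_rows = sub[sub["architecture"] == arch]
            if duf_rows.empty:
                continue
            carriers += 1
            anchor = sub[sub["architecture"].isin(retained)]
            if anchor.empty:
                continue
            for _, row in duf_rows.iterrows():
                near = anchor[
                    (anchor["gene_id"] != row["gene_id"])
                    & ((anchor["position"] - row["position"]).abs() <= window)
                ]
                if not near.empty:
                    colocal += 1
                    break
        if carriers > 0 and colocal / carriers >= min_fraction:
            kept.add(arch)
        else:
            unresolved.add(arch)
    return frozenset(kept), frozenset(unresolved)


@dataclass
class DesignSummary:
    """Final design: retained entries, category counts, supplements."""

    table: pd.DataFrame
    category_counts: pd.DataFrame   # per category: genes, domains
    known_gene_total: int
    unknown_entry_total: int
    grand_total: int
    supplements: tuple[str, ...]


def summarize_design(
    evidence: pd.DataFrame, supplements: Iterable[str] = REFERENCE_VITAMINS
) -> DesignSummary:
    """Category/gene/domain totals of the design, computed from the table.

    ``excluded`` entries are dropped from the design; the known-function gene
    total sums the five known categories; the grand total adds the
    unknown-function entries. Output row order is deterministic (category,
    then entry ID).
    """
    supplements = tuple(supplements)
    ev = evidence.copy()
    if "n_domains" not in ev.columns:
        ev["n_domains"] = 1
    overlap = set(supplements) & set(ev.index)
    if overlap:
        raise ConfigError(f"vitamin list overlaps gene list: {sorted(overlap)}")
    retained = ev[ev["category"] != EXCLUDED_CATEGORY]
    order = {c: i for i, c in enumerate(CATEGORIES)}
    retained = retained.sort_index(kind="mergesort").sort_values(
        by=["category"], key=lambda s: s.map(order), kind="mergesort"
    )
    counts = (
        retained.groupby("category", sort=False)
        .agg(genes=("n_domains", "size"), domains=("n_domains", "sum"))
    )
    known = int(counts["genes"].reindex(list(KNOWN_CATEGORIES), fill_value=0).sum())
    unknown = int(counts["genes"].get(UNKNOWN_CATEGORY, 0))
    return DesignSummary(
        table=retained,
        category_counts=counts,
        known_gene_total=known,
        unknown_entry_total=unknown,
        grand_total=known + unknown,
        supplements=supplements,
    )
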