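"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study inputs:

* a two-lifestyle genome collection with planted shared-core,
  aerobe-specific, anaerobe-specific and accessory domain architectures
  (presence perturbed by dropout and cross-group contamination), including
  gene-order coordinates that co-localise planted anaerobe-specific genes
  in operon blocks;
* a negative-binomial RNA-seq count matrix over environmental conditions
  with an anaerobic reference condition and planted consistently up/down
  regulated genes, weakly regulated decoys and per-gene dropout conditions
  that exercise the imputation rule;
* a deterministic toy metabolic model with aerobic respiration, an
  insertable denitrification pathway, and three oxygen-dependent cofactor
  syntheses (B12-, B6- and K2-like) feeding biomass.

All generators are deterministic under a fixed seed and emit the same
tab-separated formats the ingest functions read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .domains import ArchitectureMatrix, DomainHit, KEY_SEPARATOR, matrix_from_hits
from .exceptions import ConfigError
from .fba import MetabolicModel, Medium, Reaction
from .persistence import AEROBIC, ANAEROBIC
from .transcriptome import CountMatrix

SHARED_CORE = "shared_core"
AEROBE_SPECIFIC = "aerobe_specific"
ANAEROBE_SPECIFIC = "anaerobe_specific"
ACCESSORY = "accessory"


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_aerobic: int = 200
    n_anaerobic: int = 200
    n_shared_core: int = 50
    n_aerobe_specific: int = 10
    n_anaerobe_specific: int = 20
    n_accessory: int = 200
    dropout_rate: float = 0.02
    contamination_rate: float = 0.005
    genes_per_strain: int = 3000
    operon_block_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_aerobic", "n_anaerobic", "n_shared_core", "n_aerobe_specific",
            "n_anaerobe_specific", "n_accessory", "genes_per_strain",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("dropout_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.operon_block_size < 1:
            raise ConfigError(f"operon_block_size must be >= 1, got {self.operon_block_size}")


@dataclass(frozen=True)
class SyntheticTranscriptomeConfig:
    n_genes: int = 2000
    n_conditions: int = 14
    replicates_per_condition: int = 3
    extra_replicate_conditions: int = 5
    reference_condition: str = "anaerobic"
    n_planted_up: int = 60
    n_planted_down: int = 60
    planted_fold: float = 8.0
    n_planted_weak: int = 30
    dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    dropout_conditions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ConfigError(f"n_conditions must be >= 2, got {self.n_conditions}")
        if self.replicates_per_condition < 1:
            raise ConfigError(
                f"replicates_per_condition must be >= 1, got {self.replicates_per_condition}"
            )
        if self.planted_fold < 1:
            raise ConfigError(f"planted_fold must be >= 1, got {self.planted_fold}")
        n_planted = self.n_planted_up + self.n_planted_down + self.n_planted_weak
        if n_planted > self.n_genes:
            raise ConfigError("planted gene counts exceed n_genes")
        if self.dropout_conditions < 0 or self.dropout_conditions > self.n_conditions - 1:
            raise ConfigError(
                f"dropout_conditions must be in [0, n_conditions-1], got "
                f"{self.dropout_conditions}"
            )


@dataclass
class TruthLabels:
    """Planted ground truth keyed by architecture / gene."""

    architecture_category: dict[str, str] = field(default_factory=dict)
    de_gene_direction: dict[str, str] = field(default_factory=dict)

    def architectures_of(self, category: str) -> frozenset[str]:
        return frozenset(
            a for a, c in self.architecture_category.items() if c == category
        )

    def genes_of(self, direction: str) -> frozenset[str]:
        return frozenset(g for g, d in self.de_gene_direction.items() if d == direction)


# ---------------------------------------------------------------------------
# genome / domain-architecture generator


def _architecture_accessions(category_code: int, index: int, two_domain: bool) -> list[str]:
    base = f"PF{category_code}{index:04d}"
    if two_domain:
        return [base, f"PF8{category_code}{index:03d}"]
    return [base]


def _generate_domain_parts(
    cfg: SyntheticGenomeConfig,
) -> tuple[pd.DataFrame, list[DomainHit], pd.DataFrame, TruthLabels]:
    """Generate (label table, annotation hits, gene coordinates, truth).

    Planted presence probabilities: shared-core architectures in every strain
    with probability 1 - dropout_rate; group-specific architectures in the
    focal group with 1 - dropout_rate and in the other group with
    contamination_rate; accessory architectures with one random per-
    architecture background frequency common to both groups (no signal).
    Coordinates are 1-based gene-order indices; anaerobe-specific genes are
    laid out in consecutive operon blocks of ``operon_block_size``.
    """
    rng = np.random.default_rng(cfg.seed)
    strains = [f"AER{i:04d}" for i in range(cfg.n_aerobic)] + [
        f"ANA{i:04d}" for i in range(cfg.n_anaerobic)
    ]
    lifestyles = [AEROBIC] * cfg.n_aerobic + [ANAEROBIC] * cfg.n_anaerobic
    labels = pd.DataFrame({"strain_id": strains, "lifestyle": lifestyles})

    # every 5th planted architecture is two-domain, to exercise key ordering
    def make_keys(code: int, n: int) -> list[list[str]]:
        return [_architecture_accessions(code, i, i % 5 == 4) for i in range(n)]

    groups = {
        SHARED_CORE: make_keys(1, cfg.n_shared_core),
        AEROBE_SPECIFIC: make_keys(2, cfg.n_aerobe_specific),
        ANAEROBE_SPECIFIC: make_keys(3, cfg.n_anaerobe_specific),
        ACCESSORY: make_keys(4, cfg.n_accessory),
    }
    truth = TruthLabels(
        architecture_category={
            KEY_SEPARATOR.join(accs): cat
            for cat, arch_list in groups.items()
            for accs in arch_list
        }
    )
    accessory_freq = rng.uniform(0.05, 0.6, size=cfg.n_accessory)

    hits: list[DomainHit] = []
    coord_rows: list[tuple[str, str, int, str]] = []
    n_strains = len(strains)

    # presence draws, vectorized per category
    def draws(p_aer: np.ndarray, p_ana: np.ndarray, n_arch: int) -> np.ndarray:
        u = rng.random((n_strains, n_arch))
        p = np.empty((n_strains, n_arch))
        p[: cfg.n_aerobic] = p_aer
        p[cfg.n_aerobic:] = p_ana
        return u < p

    keep = 1.0 - cfg.dropout_rate
    pres = {
        SHARED_CORE: draws(np.full(cfg.n_shared_core, keep), np.full(cfg.n_shared_core, keep), cfg.n_shared_core),
        AEROBE_SPECIFIC: draws(
            np.full(cfg.n_aerobe_specific, keep),
            np.full(cfg.n_aerobe_specific, cfg.contamination_rate),
            cfg.n_aerobe_specific,
        ),
        ANAEROBE_SPECIFIC: draws(
            np.full(cfg.n_anaerobe_specific, cfg.contamination_rate),
            np.full(cfg.n_anaerobe_specific, keep),
            cfg.n_anaerobe_specific,
        ),
        ACCESSORY: draws(accessory_freq, accessory_freq, cfg.n_accessory),
    }

    for si, strain in enumerate(strains):
        carried: list[tuple[str, list[str]]] = []  # (category, accessions)
        for cat in (SHARED_CORE, AEROBE_SPECIFIC, ANAEROBE_SPECIFIC, ACCESSORY):
            for ai, present in enumerate(pres[cat][si]):
                if present:
                    carried.append((cat, groups[cat][ai]))
        # positions: anaerobe-specific genes in operon blocks at the front of
        # the coordinate space, everything else scattered behind them
        ana = [accs for cat, accs in carried if cat == ANAEROBE_SPECIFIC]
        other = [accs for cat, accs in carried if cat != ANAEROBE_SPECIFIC]
        positions: list[tuple[int, list[str]]] = []
        pos = 1
        block_left = 0
        for accs in ana:
            if block_left == 0:
                pos += 7  # intergenic gap between operon blocks
                block_left = cfg.operon_block_size
            positions.append((pos, accs))
            pos += 1
            block_left -= 1
        first_free = pos + 7
        n_other = len(other)
        span = max(cfg.genes_per_strain - first_free, n_other)
        scatter = first_free + rng.choice(span, size=n_other, replace=False)
        for p, accs in zip(sorted(scatter), other):
            positions.append((int(p), accs))
        for p, accs in positions:
            gene_id = f"{strain}_g{p:05d}"
            coord_rows.append((strain, gene_id, p, KEY_SEPARATOR.join(accs)))
            for di, acc in enumerate(accs):
                hits.append(
                    DomainHit(
                        strain_id=strain,
                        protein_id=gene_id,
                        domain_accession=acc,
                        start=10 + 100 * di,
                        end=80 + 100 * di,
                    )
                )

    coords = pd.DataFrame(
        coord_rows, columns=["strain_id", "gene_id", "position", "architecture"]
    )
    return labels, hits, coords, truth


def generate_domain_dataset(
    cfg: SyntheticGenomeConfig,
) -> tuple[pd.DataFrame, ArchitectureMatrix, pd.DataFrame, TruthLabels]:
    """Generate (label table, architecture matrix, gene coordinates, truth)."""
    labels, hits, coords, truth = _generate_domain_parts(cfg)
    return labels, matrix_from_hits(hits, labels), coords, truth


def domain_hits_table(cfg: SyntheticGenomeConfig) -> str:
    """Annotation table (TSV text) for the same dataset as the generator."""
    from .domains import write_domain_annotations

    _, hits, _, _ = _generate_domain_parts(cfg)
    return write_domain_annotations(hits)


# ---------------------------------------------------------------------------
# transcriptome generator


def generate_transcriptome(
    cfg: SyntheticTranscriptomeConfig,
) -> tuple[CountMatrix, TruthLabels]:
    """Negative-binomial counts with planted consistent regulation.

    Planted ``up`` genes have expected normalized means ``planted_fold`` times
    higher in the reference condition than in every other condition (``down``
    symmetric). ``weak`` genes are constructed to fail the default
    consistency rule deterministically: strongly up vs only
    ``ceil((k+1)/2) - 1`` of the k comparisons and mildly down (2-fold) vs
    the rest, so neither direction can reach both the consistency and the
    strong-fold-change quota. Per-sample library-size factors are drawn
    log-uniformly in [0.5, 2].
    """
    rng = np.random.default_rng(cfg.seed)
    conditions = [cfg.reference_condition] + [
        f"cond{i:02d}" for i in range(1, cfg.n_conditions)
    ]
    reps = {c: cfg.replicates_per_condition for c in conditions}
    for c in conditions[1 : 1 + cfg.extra_replicate_conditions]:
        reps[c] += 1
    samples, cond_of = [], []
    for c in conditions:
        for r in range(reps[c]):
            samples.append(f"{c}_r{r + 1}")
            cond_of.append(c)

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    n_cmp = cfg.n_conditions - 1
    base = np.exp(
        rng.uniform(np.log(cfg.base_mean_range[0]), np.log(cfg.base_mean_range[1]), cfg.n_genes)
    )
    means = np.tile(base[:, None], (1, cfg.n_conditions))  # genes x conditions

    truth = TruthLabels()
    i = 0
    up_idx = list(range(i, i + cfg.n_planted_up)); i += cfg.n_planted_up
    down_idx = list(range(i, i + cfg.n_planted_down)); i += cfg.n_planted_down
    weak_idx = list(range(i, i + cfg.n_planted_weak)); i += cfg.n_planted_weak
    for j in up_idx:
        means[j, 0] = base[j] * cfg.planted_fold
        truth.de_gene_direction[genes[j]] = "up"
    for j in down_idx:
        means[j, 0] = base[j] / cfg.planted_fold
        truth.de_gene_direction[genes[j]] = "down"
    n_weak_up = max(int(np.ceil((n_cmp + 1) / 2)) - 1, 0)
    for j in weak_idx:
        # reference at base; strongly below-base conditions -> apparent "up"
        # in too few comparisons; mildly above-base elsewhere
        means[j, 1 : 1 + n_weak_up] = base[j] / cfg.planted_fold
        means[j, 1 + n_weak_up :] = base[j] * 2.0
        truth.de_gene_direction[genes[j]] = "weak"
    for j in range(i, cfg.n_genes):
        truth.de_gene_direction[genes[j]] = "null"

    # per-gene dropout conditions (planted up/down genes only)
    for j in up_idx + down_idx:
        if cfg.dropout_conditions > 0:
            drop = rng.choice(np.arange(1, cfg.n_conditions), size=cfg.dropout_conditions, replace=False)
            means[j, drop] = 0.0

    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(samples)))
    cond_index = {c: k for k, c in enumerate(conditions)}
    mu = np.empty((cfg.n_genes, len(samples)))
    for s, (sample, c) in enumerate(zip(samples, cond_of)):
        mu[:, s] = means[:, cond_index[c]] * lib[s]

    if cfg.dispersion <= 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / cfg.dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p_param = np.where(mu > 0, n_param / (n_param + mu), 1.0)
        counts = rng.negative_binomial(n_param, p_param)
        counts[mu == 0] = 0
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples),
        condition_map=pd.Series(cond_of, index=samples, name="condition"),
        reference=cfg.reference_condition,
    )
    return cm, truth


def gene_architecture_catalog(
    de_truth: TruthLabels, arch_truth: TruthLabels, seed: int = 0
) -> dict[str, str]:
    """Gene -> architecture catalog for the synthetic transcriptome organism.

    Planted up/down genes map onto planted anaerobe-specific architectures
    (cycled); weak and null genes map onto accessory architectures, so the
    transcriptome evidence converges on the planted design targets.
    """
    ana = sorted(arch_truth.architectures_of(ANAEROBE_SPECIFIC))
    acc = sorted(arch_truth.architectures_of(ACCESSORY))
    catalog: dict[str, str] = {}
    planted = sorted(de_truth.genes_of("up") | de_truth.genes_of("down"))
    others = sorted(de_truth.genes_of("weak"))
    for k, g in enumerate(planted):
        if ana:
            catalog[g] = ana[k % len(ana)]
    for k, g in enumerate(others):
        if acc:
            catalog[g] = acc[k % len(acc)]
    return catalog


# ---------------------------------------------------------------------------
# toy metabolic model

DENITRIFICATION_REACTIONS = ("NAR", "NIR", "NOR", "NOS")
VITAMIN_EXCHANGES = ("EX_b12", "EX_b6", "EX_k2")
COFACTOR_METABOLITES = ("b12", "b6", "k2")
GLUCOSE_UPTAKE = 6.14  # mmol gdw^-1 h^-1, measured maximal carbon uptake


def generate_toy_model() -> MetabolicModel:
    """Deterministic desk-scale metabolic model for the oxygen-gap analysis.

    Carbon enters as a generic sugar; glycolysis yields pyruvate, ATP and
    NADH; NADH is reoxidized either by O2 respiration or by an *insertable*
    four-step denitrification chain (nitrate -> nitrite -> NO -> N2O -> N2,
    each step conserving energy). Three cofactors (B12-, B6- and K2-like)
    require O2 for synthesis, have closed uptake exchanges, and are biomass
    precursors together with ATP and pyruvate. Without any electron sink the
    network carries no flux, so anoxic growth is impossible unless
    denitrification is enabled, and even then the cofactors remain blocked
    until their exchanges are opened.
    """

    def rxn(rid: str, eq: str, lo: float = 0.0, hi: float = 1000.0,
            genes: tuple[str, ...] = (), insertable: bool = False) -> Reaction:
        from .fba import parse_equation

        return Reaction(rid, parse_equation(eq), lo, hi, genes, insertable)

    reactions = {
        "EX_glc": rxn("EX_glc", "1 glc_e ->", -GLUCOSE_UPTAKE, 1000.0),
        "T_glc": rxn("T_glc", "1 glc_e -> 1 glc"),
        "GLYC": rxn("GLYC", "1 glc -> 2 pyr + 2 atp + 2 nadh", genes=("edd", "eda")),
        "EX_o2": rxn("EX_o2", "1 o2_e ->", -1000.0, 1000.0),
        "T_o2": rxn("T_o2", "1 o2_e -> 1 o2"),
        "RESP": rxn("RESP", "2 nadh + 1 o2 -> 4 atp", genes=("cyoA", "cyoB")),
        "B12S": rxn("B12S", "1 pyr + 1 o2 -> 1 b12", genes=("cobG", "cobNST")),
        "B6S": rxn("B6S", "1 pyr + 1 o2 -> 1 b6", genes=("pdxH",)),
        "K2S": rxn("K2S", "1 pyr + 1 o2 -> 1 k2", genes=("menG", "ubiE")),
        "EX_b12": rxn("EX_b12", "1 b12_e ->", 0.0, 1000.0),
        "T_b12": rxn("T_b12", "1 b12_e -> 1 b12", genes=("btuB",)),
        "EX_b6": rxn("EX_b6", "1 b6_e ->", 0.0, 1000.0),
        "T_b6": rxn("T_b6", "1 b6_e -> 1 b6"),
        "EX_k2": rxn("EX_k2", "1 k2_e ->", 0.0, 1000.0),
        "T_k2": rxn("T_k2", "1 k2_e -> 1 k2"),
        "EX_no3": rxn("EX_no3", "1 no3_e ->", -1000.0, 1000.0),
        "T_no3": rxn("T_no3", "1 no3_e -> 1 no3", genes=("narK1", "narK2")),
        "NAR": rxn("NAR", "1 no3 + 1 nadh -> 1 no2 + 2 atp",
                   genes=("narG", "narH", "narI"), insertable=True),
        "NIR": rxn("NIR", "1 no2 + 1 nadh -> 1 no + 1 atp",
                   genes=("nirS",), insertable=True),
        "NOR": rxn("NOR", "2 no + 1 nadh -> 1 n2o + 1 atp",
                   genes=("norB", "norC"), insertable=True),
        "NOS": rxn("NOS", "1 n2o + 1 nadh -> 1 n2 + 1 atp",
                   genes=("nosZ",), insertable=True),
        "EX_n2": rxn("EX_n2", "1 n2 ->", 0.0, 1000.0),
        # overflow sinks: excess ATP is hydrolysed (maintenance), excess
        # pyruvate is secreted, so growth is substrate- not balance-limited
        "ATPM": rxn("ATPM", "1 atp ->", 0.0, 1000.0),
        "EX_pyr": rxn("EX_pyr", "1 pyr ->", 0.0, 1000.0),
        "biomass": rxn(
            "biomass", "10 atp + 1 pyr + 0.1 b12 + 0.1 b6 + 0.1 k2 ->"
        ),
    }
    metabolites = sorted({m for r in reactions.values() for m in r.stoich})
    model = MetabolicModel(metabolites=metabolites, reactions=reactions, objective="biomass")
    model.validate()
    return model


def toy_medium() -> Medium:
    """Aerobic minimal medium for the toy model (carbon 6.14, O2 and nitrate open)."""
    return Medium(
        uptakes={"EX_glc": GLUCOSE_UPTAKE, "EX_o2": 1000.0, "EX_no3": 1000.0},
        oxygen_exchange="EX_o2",
    )


# ---------------------------------------------------------------------------
# writers (round-trip formats)


def write_labels(labels: pd.DataFrame) -> str:
    return labels.to_csv(sep="\t", index=False)


def read_labels(text_or_path) -> pd.DataFrame:
    import io as _io

    if isinstance(text_or_path, str) and "\n" in text_or_path:
        text_or_path = _io.StringIO(text_or_path)
    return pd.read_csv(text_or_path, sep="\t", dtype={"strain_id": str, "lifestyle": str})


def write_counts(cm: CountMatrix) -> tuple[str, str]:
    """(counts TSV, condition-map TSV) pair."""
    counts = cm.counts.to_csv(sep="\t")
    cond = cm.condition_map.rename_axis("sample").to_frame().to_csv(sep="\t")
    return counts, cond


def read_counts(counts_src, condition_src, reference: str) -> CountMatrix:
    import io as _io

    def as_stream(x):
        return _io.StringIO(x) if isinstance(x, str) and "\n" in x else x

    counts = pd.read_csv(as_stream(counts_src), sep="\t", index_col=0)
    cond = pd.read_csv(as_stream(condition_src), sep="\t", index_col=0)["condition"]
    return CountMatrix(counts=counts, condition_map=cond, reference=reference)
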