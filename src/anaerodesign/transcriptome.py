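"""Condition-wise fold changes against an anaerobic reference and the
direction-consistency filter.

Counts are normalized with median-of-ratios size factors; replicates are
collapsed by mean of normalized counts; each non-reference condition is
compared with the reference as log2(reference / condition), so positive
values mean up-regulation during anaerobic respiration. Non-finite fold
changes from zero counts are imputed to 0 or +/-4 according to a BH-adjusted
fdr. A gene is selected when its direction agrees in at least
``min_consistent`` of the comparisons and at least ``min_strong`` of those
same-direction comparisons reach the strong fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, LabelError, NormalizationError, PreconditionError

IMPUTE_MAGNITUDE = 4.0  # imputed log2 fold change for significant inf cells


@dataclass(frozen=True)
class ConsistencyRule:
    """Selection rule over per-condition log2 fold changes."""

    min_consistent: int = 7
    min_strong: int = 3
    strong_fold: float = 4.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.min_strong <= self.min_consistent:
            raise ConfigError(
                f"need 1 <= min_strong <= min_consistent, got "
                f"min_strong={self.min_strong}, min_consistent={self.min_consistent}"
            )
        if self.strong_fold < 1:
            raise ConfigError(f"strong_fold must be >= 1, got {self.strong_fold}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")

    @property
    def strong_log2(self) -> float:
        return float(np.log2(self.strong_fold))


@dataclass
class CountMatrix:
    """Genes x samples counts with a sample -> condition map."""

    counts: pd.DataFrame
    condition_map: pd.Series  # index: sample, value: condition label
    reference: str

    def __post_init__(self) -> None:
        unmapped = [s for s in self.counts.columns if s not in self.condition_map.index]
        if unmapped:
            raise LabelError(f"samples without condition label: {unmapped}")
        if self.reference not in set(self.condition_map.values):
            raise LabelError(f"reference condition {self.reference!r} has no samples")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_map[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_map[s] == condition]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference per gene is the geometric mean across samples over genes
    with no zero count; each sample's factor is the median ratio to that
    reference.
    """
    arr = counts.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    log_arr = np.log(arr[eligible])
    log_geo = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors(cm.counts)


def condition_means(cm: CountMatrix) -> pd.DataFrame:
    """Mean normalized count per gene and condition (replicates collapsed)."""
    norm = normalized_counts(cm)
    return pd.DataFrame(
        {c: norm[cm.samples_of(c)].mean(axis=1) for c in cm.conditions}
    )


def _per_gene_fdr(norm: pd.DataFrame, ref_samples: list[str], cond_samples: list[str]) -> pd.Series:
    """BH-adjusted two-group Welch test on log2(normalized + 0.5)."""
    a = np.log2(norm[ref_samples].to_numpy() + 0.5)
    b = np.log2(norm[cond_samples].to_numpy() + 0.5)
    if a.shape[1] < 2 or b.shape[1] < 2:
        # too few replicates for a dispersion estimate: no evidence
        return pd.Series(1.0, index=norm.index)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate groups trigger precision-loss warnings;
        # those genes get p ~ 1 and never gate an imputation
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.Series(fdr, index=norm.index)


def condition_log2fc(cm: CountMatrix, condition: str) -> pd.DataFrame:
    """Per-gene (log2fc, fdr) for one condition vs the anaerobic reference.

    log2fc = log2(mean normalized reference count / mean normalized condition
    count); zero means give +/-inf or NaN, which downstream imputation
    resolves. The fdr backs that imputation only.
    """
    if condition == cm.reference:
        raise ConfigError("condition must differ from the reference")
    if condition not in cm.conditions:
        raise LabelError(f"unknown condition {condition!r}")
    norm = normalized_counts(cm)
    ref_samples = cm.samples_of(cm.reference)
    cond_samples = cm.samples_of(condition)
    ref_mean = norm[ref_samples].mean(axis=1)
    cond_mean = norm[cond_samples].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(ref_mean.to_numpy() / cond_mean.to_numpy())
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "fdr": _per_gene_fdr(norm, ref_samples, cond_samples),
        },
        index=cm.counts.index,
    )


def impute_log2fc(value: float, fdr: float, rule: ConsistencyRule) -> tuple[float, bool]:
    """Imputation rule for one cell; returns (value, imputed_flag).

    Finite values pass through. +/-inf becomes +/-4 when the differential
    expression is significant (fdr < alpha), else 0. NaN (0/0: absent in both
    groups) has no defined direction and becomes 0.
    """
    if np.isfinite(value):
        return float(value), False
    if np.isnan(value):
        return 0.0, True
    if fdr < rule.alpha:
        return float(np.sign(value) * IMPUTE_MAGNITUDE), True
    return 0.0, True


@dataclass
class Log2FCMatrix:
    """Genes x non-reference conditions, fully imputed."""

    log2fc: pd.DataFrame
    fdr: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask

    @property
    def comparisons(self) -> list[str]:
        return list(self.log2fc.columns)


def log2fc_matrix(cm: CountMatrix, rule: ConsistencyRule | None = None) -> Log2FCMatrix:
    """All pairwise comparisons vs the reference, imputed per the rule."""
    rule = rule or ConsistencyRule()
    lfc_cols, fdr_cols, imp_cols = {}, {}, {}
    for cond in cm.conditions:
        if cond == cm.reference:
            continue
        res = condition_log2fc(cm, cond)
        vals = np.empty(len(res))
        flags = np.empty(len(res), dtype=bool)
        for i, (v, f) in enumerate(zip(res["log2fc"], res["fdr"])):
            vals[i], flags[i] = impute_log2fc(v, f, rule)
        lfc_cols[cond] = pd.Series(vals, index=res.index)
        fdr_cols[cond] = res["fdr"]
        imp_cols[cond] = pd.Series(flags, index=res.index)
    return Log2FCMatrix(
        log2fc=pd.DataFrame(lfc_cols),
        fdr=pd.DataFrame(fdr_cols),
        imputed=pd.DataFrame(imp_cols),
    )


def consistency_filter(fc: Log2FCMatrix, rule: ConsistencyRule | None = None) -> pd.DataFrame:
    """Genes with consistent, partly strong regulation vs the reference.

    A gene is selected with direction ``up`` (``down``) when at least
    ``min_consistent`` comparisons have positive (negative) log2fc and at
    least ``min_strong`` of those same-direction comparisons have
    |log2fc| >= log2(strong_fold). Zero cells count for neither direction.
    """
    rule = rule or ConsistencyRule()
    vals = fc.log2fc.to_numpy()
    if not np.isfinite(vals).all():
        raise PreconditionError("consistency_filter requires a fully imputed matrix")
    strong = np.abs(vals) >= rule.strong_log2
    n_pos = (vals > 0).sum(axis=1)
    n_neg = (vals < 0).sum(axis=1)
    n_pos_strong = ((vals > 0) & strong).sum(axis=1)
    n_neg_strong = ((vals < 0) & strong).sum(axis=1)
    rows = []
    for i, gene in enumerate(fc.log2fc.index):
        if n_pos[i] >= rule.min_consistent and n_pos_strong[i] >= rule.min_strong:
            rows.append((gene, "up", int(n_pos[i]), int(n_pos_strong[i])))
        elif n_neg[i] >= rule.min_consistent and n_neg_strong[i] >= rule.min_strong:
            rows.append((gene, "down", int(n_neg[i]), int(n_neg_strong[i])))
    return pd.DataFrame(
        rows, columns=["gene", "direction", "n_consistent", "n_strong"]
    ).set_index("gene")


def map_genes_to_architectures(
    genes: list[str] | pd.Index, catalog: Mapping[str, str]
) -> tuple[frozenset[str], list[str]]:
    """Map selected genes to domain-architecture keys.

    ``catalog`` maps gene/protein IDs of the transcriptome organism to
    architecture keys. Returns (architecture set, unmapped gene list); genes
    without annotation are reported, never silently dropped.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        if g in catalog:
            mapped.add(catalog[g])
        else:
            unmapped.append(g)
    return frozenset(mapped), unmapped
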