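"""Gene persistence, threshold cores, and ordination/clustering of genomes.

Persistence of an ortholog in a group of genomes is N(orth)/N: the fraction
of group genomes carrying it. A *domain core* at threshold tau is the set of
architectures with persistence >= tau; comparing the aerobic and anaerobic
cores by set algebra yields shared / aerobe-specific / anaerobe-specific
lists. A complementary rule flags architectures nearly absent (<= epsilon)
from one lifestyle group but persistent in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA

from .domains import ArchitectureMatrix
from .exceptions import ConfigError, LabelError

AEROBIC = "aerobic"
ANAEROBIC = "anaerobic"
LIFESTYLES = (AEROBIC, ANAEROBIC)


def group_strains(labels: pd.DataFrame, lifestyle: str) -> list[str]:
    """Strain IDs of one lifestyle group from the label table."""
    if lifestyle not in LIFESTYLES:
        raise ConfigError(f"unknown lifestyle {lifestyle!r}; expected one of {LIFESTYLES}")
    return list(labels.loc[labels["lifestyle"] == lifestyle, "strain_id"])


def persistence(matrix: ArchitectureMatrix | pd.DataFrame, group: list[str]) -> pd.Series:
    """Per-architecture persistence N(orth)/N within ``group``.

    ``matrix`` may be an :class:`ArchitectureMatrix` (its binary view is used)
    or any presence/count DataFrame indexed by strain.
    """
    df = matrix.binary if isinstance(matrix, ArchitectureMatrix) else matrix
    if len(group) == 0:
        raise ConfigError("persistence: empty strain group")
    missing = [s for s in group if s not in df.index]
    if missing:
        raise LabelError(f"strains not in matrix: {missing}")
    sub = df.loc[group]
    return (sub > 0).sum(axis=0) / len(group)


def persistence_table(
    matrix: ArchitectureMatrix | pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Two-column table (aerobic, anaerobic) of per-architecture persistence."""
    return pd.DataFrame(
        {g: persistence(matrix, group_strains(labels, g)) for g in LIFESTYLES}
    )


def core_at_threshold(pt: pd.Series, tau: float) -> frozenset[str]:
    """Architectures with persistence >= tau (the group's domain core)."""
    if not 0 < tau <= 1:
        raise ConfigError(f"core threshold tau={tau} outside (0, 1]")
    return frozenset(pt.index[pt >= tau])


@dataclass(frozen=True)
class CoreSplit:
    """Disjoint shared / lifestyle-specific architecture sets."""

    shared: frozenset[str]
    aerobe_specific: frozenset[str]
    anaerobe_specific: frozenset[str]
    thresholds: tuple[float, ...] = ()
    scope: str = "full"

    def __post_init__(self) -> None:
        if (
            self.shared & self.aerobe_specific
            or self.shared & self.anaerobe_specific
            or self.aerobe_specific & self.anaerobe_specific
        ):
            raise ConfigError("CoreSplit sets must be pairwise disjoint")


def split_cores(
    core_aerobic: frozenset[str] | set[str],
    core_anaerobic: frozenset[str] | set[str],
    thresholds: tuple[float, ...] = (),
    scope: str = "full",
) -> CoreSplit:
    """Set-algebra split of two lifestyle cores."""
    a, b = frozenset(core_aerobic), frozenset(core_anaerobic)
    return CoreSplit(
        shared=a & b,
        aerobe_specific=a - b,
        anaerobe_specific=b - a,
        thresholds=thresholds,
        scope=scope,
    )


def specific_by_low_persistence(
    pt_aerobic: pd.Series,
    pt_anaerobic: pd.Series,
    epsilon: float = 0.01,
    tau_presence: float = 0.95,
    scope: str = "full",
) -> CoreSplit:
    """Specificity by near-absence from the opposite lifestyle.

    An architecture is anaerobe-specific when its persistence among aerobic
    genomes is <= epsilon while it is persistent (>= tau_presence) among
    anaerobic genomes; symmetrically for aerobe-specific. Architectures
    persistent in both groups form the shared set. The presence requirement
    keeps universally-absent architectures out of the specific lists.
    """
    if not 0 <= epsilon < tau_presence <= 1:
        raise ConfigError(
            f"need 0 <= epsilon < tau_presence <= 1, got epsilon={epsilon}, "
            f"tau_presence={tau_presence}"
        )
    pa, pn = pt_aerobic.align(pt_anaerobic, fill_value=0.0)
    anaerobe = frozenset(pa.index[(pa <= epsilon) & (pn >= tau_presence)])
    aerobe = frozenset(pa.index[(pn <= epsilon) & (pa >= tau_presence)])
    shared = frozenset(pa.index[(pa >= tau_presence) & (pn >= tau_presence)])
    return CoreSplit(
        shared=shared,
        aerobe_specific=aerobe,
        anaerobe_specific=anaerobe,
        thresholds=(epsilon, tau_presence),
        scope=scope,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame            # strains x components
    variance_fractions: np.ndarray  # per-component fraction of total variance


def run_pca(binary: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the presence/absence matrix (columns centered, not scaled).

    Degenerate input (all strains identical, zero total variance) returns
    all-zero scores and variance fractions rather than failing.
    """
    X = binary.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ConfigError("PCA needs at least 2 strains and 2 architectures")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    k = min(X.shape) if n_components is None else n_components
    k = min(k, min(X.shape[0] - 1, X.shape[1]))
    if total_var <= 1e-12:
        scores = pd.DataFrame(
            np.zeros((X.shape[0], k)), index=binary.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return PCAResult(scores=scores, variance_fractions=np.zeros(k))
    pca = PCA(n_components=k, svd_solver="full")
    sc = pca.fit_transform(Xc)
    scores = pd.DataFrame(sc, index=binary.index, columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(scores=scores, variance_fractions=pca.explained_variance_ratio_)


@dataclass
class Dendrogram:
    """Hierarchical clustering of strains on presence/absence profiles."""

    linkage: np.ndarray
    leaves: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaves)
        return str(tree)


def hierarchical_tree(
    binary: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering (default: complete linkage, Euclidean)."""
    Z = sch.linkage(binary.to_numpy(dtype=float), method=method, metric=metric)
    return Dendrogram(linkage=Z, leaves=list(binary.index))


def extract_branch(dendro: Dendrogram, focal_strain: str, depth: int) -> list[str]:
    """Leaf set of the subtree containing ``focal_strain``.

    Starting from the root, descend ``depth`` binary splits, each time taking
    the child whose leaves include the focal strain; return that subtree's
    leaves (in the input strain order). ``depth=0`` returns all strains.
    """
    if focal_strain not in dendro.leaves:
        raise LabelError(f"focal strain {focal_strain!r} not in dendrogram")
    if depth < 0:
        raise ConfigError(f"depth must be >= 0, got {depth}")
    node = sch.to_tree(dendro.linkage)
    focal_idx = dendro.leaves.index(focal_strain)
    for _ in range(depth):
        if node.is_leaf():
            break
        left_ids = set(node.get_left().pre_order(lambda n: n.id))
        node = node.get_left() if focal_idx in left_ids else node.get_right()
    ids = sorted(node.pre_order(lambda n: n.id))
    return [dendro.leaves[i] for i in ids]


def export_lists(
    pt: pd.DataFrame, splits: dict[str, CoreSplit]
) -> pd.DataFrame:
    """Tabular export: persistence values plus list membership flags."""
    out = pt.rename(columns={AEROBIC: "persistence_aerobic", ANAEROBIC: "persistence_anaerobic"})
    out = out.copy()
    for name, split in splits.items():
        member = pd.Series("", index=out.index, dtype=object)
        member[[a for a in split.shared if a in out.index]] = "shared"
        member[[a for a in split.aerobe_specific if a in out.index]] = "aerobe_specific"
        member[[a for a in split.anaerobe_specific if a in out.index]] = "anaerobe_specific"
        out[f"list_{name}"] = member
    out.index.name = "architecture"
    return out
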