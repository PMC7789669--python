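"""Random-forest feature ranking of domain architectures.

Repeatedly trains a random-forest classifier (aerobic vs facultative
anaerobic) on balanced genome subsamples and sums each architecture's
impurity-decrease (Gini) importance over repetitions into a *cumulative Gini
coefficient*. Importances are unnormalized mean impurity decreases per model
(R randomForest MeanDecreaseGini scale: proportion-weighted decrease times
the training-sample count), so cumulative values grow with sample size and
repetitions; absolute selection thresholds are scale-dependent configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .domains import ArchitectureMatrix
from .exceptions import ConfigError, LabelError
from .persistence import AEROBIC, ANAEROBIC, LIFESTYLES


@dataclass(frozen=True)
class RFProtocolConfig:
    """Protocol parameters for repeated balanced-subsample training."""

    n_per_class: int = 300
    repetitions: int = 100
    trees_per_model: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0
    allow_smaller_classes: bool = False

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.repetitions < 1:
            raise ConfigError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.trees_per_model < 1:
            raise ConfigError(f"trees_per_model must be >= 1, got {self.trees_per_model}")


def _rep_seed(seed: int, repetition_index: int) -> int:
    # one deterministic child seed per repetition, kept below 2**31
    ss = np.random.SeedSequence([seed, repetition_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def balanced_subsample(
    labels: pd.DataFrame, cfg: RFProtocolConfig, repetition_index: int
) -> list[str]:
    """Sample ``n_per_class`` distinct strains per lifestyle class.

    Within a repetition, sampling is without replacement; repetitions use
    independent draws derived from one seed, so a strain may recur between
    repetitions. Classes smaller than ``n_per_class`` raise unless
    ``allow_smaller_classes`` is set, in which case the whole class is taken.
    """
    rng = np.random.default_rng(_rep_seed(cfg.seed, repetition_index))
    chosen: list[str] = []
    for lifestyle in LIFESTYLES:
        members = list(labels.loc[labels["lifestyle"] == lifestyle, "strain_id"])
        if not members:
            raise LabelError(f"no strains labelled {lifestyle!r}")
        if len(members) < cfg.n_per_class:
            if not cfg.allow_smaller_classes:
                raise ConfigError(
                    f"class {lifestyle!r} has {len(members)} strains, fewer than "
                    f"n_per_class={cfg.n_per_class}"
                )
            chosen.extend(members)
        else:
            chosen.extend(rng.choice(members, size=cfg.n_per_class, replace=False))
    return chosen


def train_and_importances(
    matrix: ArchitectureMatrix | pd.DataFrame,
    subset: list[str],
    labels: pd.DataFrame,
    cfg: RFProtocolConfig,
    repetition_index: int = 0,
) -> pd.Series:
    """One forest on one subsample; per-architecture Gini importance.

    Returns non-negative unnormalized mean impurity decreases; architectures
    constant on the subsample (including all-absent ones) get 0.
    """
    binary = matrix.binary if isinstance(matrix, ArchitectureMatrix) else matrix
    X = binary.loc[subset].to_numpy(dtype=np.float32)
    lab = labels.set_index("strain_id")["lifestyle"]
    y = (lab.loc[subset] == ANAEROBIC).to_numpy()
    if len(set(y)) < 2:
        raise LabelError("training subset contains a single lifestyle class")
    forest = RandomForestClassifier(
        n_estimators=cfg.trees_per_model,
        max_features=cfg.max_features,
        random_state=_rep_seed(cfg.seed + 2**20, repetition_index),
        n_jobs=1,
    )
    forest.fit(X, y)
    raw = np.zeros(X.shape[1])
    for est in forest.estimators_:
        raw += est.tree_.compute_feature_importances(normalize=False)
    raw = raw / len(forest.estimators_) * X.shape[0]
    return pd.Series(raw, index=binary.columns)


def cumulative_gini(importance_vectors: list[pd.Series]) -> pd.DataFrame:
    """Sum per-repetition importances into the cumulative Gini table.

    Returns a DataFrame indexed by architecture with columns
    ``cumulative_gini`` and ``rank`` (descending, ties broken by key).
    """
    if not importance_vectors:
        raise ConfigError("cumulative_gini: need at least one repetition")
    ref = importance_vectors[0].index
    for v in importance_vectors[1:]:
        if not ref.equals(v.index):
            raise ConfigError("cumulative_gini: repetition vectors cover different architectures")
    total = sum(importance_vectors)
    table = pd.DataFrame({"cumulative_gini": total})
    table = table.sort_values(
        by="cumulative_gini", ascending=False, kind="mergesort"
    )
    # stable sort on descending value; lexicographic key order within ties
    table = (
        table.reset_index()
        .rename(columns={"index": "architecture"})
        .sort_values(["cumulative_gini", "architecture"], ascending=[False, True], kind="mergesort")
        .set_index("architecture")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def run_protocol(
    matrix: ArchitectureMatrix | pd.DataFrame,
    labels: pd.DataFrame,
    cfg: RFProtocolConfig,
) -> pd.DataFrame:
    """Full repeated-subsample protocol: subsample, train, accumulate."""
    vectors = [
        train_and_importances(matrix, balanced_subsample(labels, cfg, r), labels, cfg, r)
        for r in range(cfg.repetitions)
    ]
    return cumulative_gini(vectors)


def select_by_gini(
    table: pd.DataFrame,
    threshold: float,
    pt_aerobic: pd.Series | None = None,
    pt_anaerobic: pd.Series | None = None,
) -> pd.DataFrame:
    """Architectures with cumulative Gini >= threshold, tagged by lifestyle.

    The specificity tag compares persistence between groups when persistence
    tables are supplied: the higher-persistence lifestyle wins, exact ties
    (or missing tables) leave the entry untagged.
    """
    if threshold < 0:
        raise ConfigError(f"gini threshold must be >= 0, got {threshold}")
    sel = table.loc[table["cumulative_gini"] >= threshold].copy()
    tags = []
    for arch in sel.index:
        tag = ""
        if pt_aerobic is not None and pt_anaerobic is not None:
            pa = float(pt_aerobic.get(arch, 0.0))
            pn = float(pt_anaerobic.get(arch, 0.0))
            if pn > pa:
                tag = "anaerobe_specific"
            elif pa > pn:
                tag = "aerobe_specific"
        tags.append(tag)
    sel["specificity_tag"] = tags
    return sel
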