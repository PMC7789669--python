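"""Persistence, threshold cores and clustering, checked against brute force."""

import numpy as np
import pandas as pd
import pytest

from anaerodesign import synthetic
from anaerodesign.exceptions import ConfigError, LabelError
from anaerodesign.persistence import (
    CoreSplit,
    core_at_threshold,
    extract_branch,
    hierarchical_tree,
    persistence,
    persistence_table,
    run_pca,
    specific_by_low_persistence,
    split_cores,
)

from conftest import random_binary_matrix


# --- independent brute-force oracles -------------------------------------

def brute_persistence(binary: pd.DataFrame, group: list[str]) -> dict[str, float]:
    out = {}
    for arch in binary.columns:
        carried = sum(1 for s in group if binary.loc[s, arch] > 0)
        out[arch] = carried / len(group)
    return out


def brute_core(pers: dict[str, float], tau: float) -> set[str]:
    return {a for a, v in pers.items() if v >= tau}


def brute_low_persistence_split(pa, pn, eps, tau):
    ana = {a for a in pa if pa[a] <= eps and pn[a] >= tau}
    aer = {a for a in pa if pn[a] <= eps and pa[a] >= tau}
    shared = {a for a in pa if pa[a] >= tau and pn[a] >= tau}
    return shared, aer, ana


# --- unit behaviour -------------------------------------------------------

class TestPersistence:
    def test_hand_counts(self):
        binary = pd.DataFrame(
            {"D": [1, 1, 1, 0]}, index=["a", "b", "c", "d"]
        )
        assert persistence(binary, ["a", "b", "c", "d"])["D"] == 0.75
        assert persistence(binary, ["a", "b", "c"])["D"] == 1.0

    def test_six_strain_toy(self, six_strain_matrix):
        matrix, labels = six_strain_matrix
        pt = persistence_table(matrix, labels)
        assert pt.loc["D3", "anaerobic"] == 1.0
        assert pt.loc["D3", "aerobic"] == 0.0

    def test_empty_group_rejected(self, six_strain_matrix):
        matrix, _ = six_strain_matrix
        with pytest.raises(ConfigError):
            persistence(matrix, [])


class TestCores:
    def test_threshold_boundary(self):
        pt = pd.Series({"in": 0.96, "out": 0.94})
        core = core_at_threshold(pt, 0.95)
        assert core == {"in"}

    def test_tau_one_is_universal_presence(self):
        pt = pd.Series({"a": 1.0, "b": 0.999})
        assert core_at_threshold(pt, 1.0) == {"a"}

    @pytest.mark.parametrize("tau", [0.0, 1.5, -0.1])
    def test_invalid_tau(self, tau):
        with pytest.raises(ConfigError):
            core_at_threshold(pd.Series({"a": 1.0}), tau)

    def test_split_set_algebra(self):
        sp = split_cores({"x", "y"}, {"y", "z"})
        assert sp.shared == {"y"}
        assert sp.aerobe_specific == {"x"}
        assert sp.anaerobe_specific == {"z"}
        same = split_cores({"x"}, {"x"})
        assert not same.aerobe_specific and not same.anaerobe_specific

    def test_disjointness_enforced(self):
        with pytest.raises(ConfigError):
            CoreSplit(frozenset("a"), frozenset("a"), frozenset())


class TestLowPersistenceRule:
    def test_rule_application(self):
        pa = pd.Series({"d": 0.005, "e": 0.02, "f": 0.0})
        pn = pd.Series({"d": 0.97, "e": 0.97, "f": 0.0})
        sp = specific_by_low_persistence(pa, pn, epsilon=0.01, tau_presence=0.95)
        assert "d" in sp.anaerobe_specific
        assert "e" not in sp.anaerobe_specific   # fails the <= 1% rule
        assert "f" not in (sp.shared | sp.aerobe_specific | sp.anaerobe_specific)

    def test_epsilon_must_undercut_presence(self):
        pa = pd.Series({"d": 0.5})
        with pytest.raises(ConfigError):
            specific_by_low_persistence(pa, pa, epsilon=0.95, tau_presence=0.95)


# --- oracle equivalence and properties ------------------------------------

def test_matches_brute_force_on_small_matrices():
    """persistence / cores / splits agree with enumeration on <= 6x8 inputs."""
    rng = np.random.default_rng(0)
    for _ in range(150):
        binary = random_binary_matrix(rng)
        group_a = list(binary.index[: max(1, len(binary) // 2)])
        group_b = list(binary.index[max(1, len(binary) // 2):]) or group_a
        tau = float(rng.uniform(0.05, 1.0))
        eps = float(rng.uniform(0.0, tau - 1e-6))
        pa, pn = persistence(binary, group_a), persistence(binary, group_b)
        bpa, bpn = brute_persistence(binary, group_a), brute_persistence(binary, group_b)
        assert pa.to_dict() == pytest.approx(bpa)
        assert core_at_threshold(pa, tau) == brute_core(bpa, tau)
        sp = split_cores(core_at_threshold(pa, tau), core_at_threshold(pn, tau))
        assert sp.shared == brute_core(bpa, tau) & brute_core(bpn, tau)
        assert sp.aerobe_specific == brute_core(bpa, tau) - brute_core(bpn, tau)
        lp = specific_by_low_persistence(pa, pn, epsilon=eps, tau_presence=tau)
        shared, aer, ana = brute_low_persistence_split(bpa, bpn, eps, tau)
        assert (set(lp.shared), set(lp.aerobe_specific), set(lp.anaerobe_specific)) == (
            shared, aer, ana,
        )


def test_bounds_and_threshold_monotonicity():
    """0 <= persistence <= 1 and tau' >= tau implies core(tau') <= core(tau)."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(2, 21))
        p = int(rng.integers(2, 51))
        binary = pd.DataFrame(
            rng.integers(0, 2, size=(n, p)),
            index=[f"S{i}" for i in range(n)],
            columns=[f"D{j}" for j in range(p)],
        )
        pt = persistence(binary, list(binary.index))
        assert ((pt >= 0) & (pt <= 1)).all()
        t1, t2 = sorted(rng.uniform(0.05, 1.0, size=2))
        assert core_at_threshold(pt, t2) <= core_at_threshold(pt, t1)


def test_planted_split_recovery_without_noise():
    cfg = synthetic.SyntheticGenomeConfig(
        n_aerobic=10, n_anaerobic=10, n_shared_core=6, n_aerobe_specific=3,
        n_anaerobe_specific=4, n_accessory=0, dropout_rate=0.0,
        contamination_rate=0.0, seed=2,
    )
    labels, matrix, _, truth = synthetic.generate_domain_dataset(cfg)
    pt = persistence_table(matrix, labels)
    sp = split_cores(
        core_at_threshold(pt["aerobic"], 0.95), core_at_threshold(pt["anaerobic"], 0.95)
    )
    assert sp.anaerobe_specific == truth.architectures_of("anaerobe_specific")
    assert sp.aerobe_specific == truth.architectures_of("aerobe_specific")
    assert truth.architectures_of("shared_core") <= sp.shared


# --- ordination and clustering --------------------------------------------

class TestPCA:
    def test_degenerate_input_reports_zero_variance(self):
        binary = pd.DataFrame(np.ones((4, 5)), index=list("abcd"))
        res = run_pca(binary)
        assert np.allclose(res.variance_fractions, 0)

    def test_variance_fractions_normalized(self):
        rng = np.random.default_rng(3)
        binary = pd.DataFrame(rng.integers(0, 2, (10, 8)))
        res = run_pca(binary)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (res.variance_fractions >= 0).all()

    def test_separated_groups_split_on_pc1(self):
        block = np.zeros((10, 6), dtype=int)
        block[:5, :3] = 1
        block[5:, 3:] = 1
        binary = pd.DataFrame(block, index=[f"S{i}" for i in range(10)])
        res = run_pca(binary)
        signs = np.sign(res.scores["PC1"].to_numpy())
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]


class TestHierarchy:
    def _pairs_matrix(self):
        mat = np.array([[1, 1, 0, 0]] * 2 + [[0, 0, 1, 1]] * 2)
        return pd.DataFrame(mat, index=["a1", "a2", "b1", "b2"])

    def test_first_split_separates_identical_pairs(self):
        dend = hierarchical_tree(self._pairs_matrix())
        branch = set(extract_branch(dend, "a1", depth=1))
        assert branch == {"a1", "a2"}

    def test_depth_zero_is_all_strains(self):
        dend = hierarchical_tree(self._pairs_matrix())
        assert set(extract_branch(dend, "b2", depth=0)) == {"a1", "a2", "b1", "b2"}

    def test_mixed_branch_contains_focal_and_both_labels(self):
        # two tight clusters; the focal one mixes lifestyles, as in a
        # restricted-list scenario
        rng = np.random.default_rng(4)
        tight = rng.integers(0, 2, size=(1, 12)).repeat(6, axis=0)
        tight = tight ^ (rng.random((6, 12)) < 0.05)
        far = 1 - tight[:3]
        binary = pd.DataFrame(
            np.vstack([tight, far]),
            index=[f"M{i}" for i in range(6)] + [f"F{i}" for i in range(3)],
        )
        dend = hierarchical_tree(binary)
        branch = set(extract_branch(dend, "M0", depth=1))
        assert "M0" in branch
        assert branch <= {f"M{i}" for i in range(6)}

    def test_unknown_focal_strain(self):
        dend = hierarchical_tree(self._pairs_matrix())
        with pytest.raises(LabelError):
            extract_branch(dend, "nope", depth=1)

    def test_newick_export_contains_all_leaves(self):
        dend = hierarchical_tree(self._pairs_matrix())
        nwk = dend.to_newick()
        for leaf in ["a1", "a2", "b1", "b2"]:
            assert leaf in nwk
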