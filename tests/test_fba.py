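"""FBA, the tabular model format, and the oxygen-gap analysis.

The LP optimum is cross-checked against (i) an independent vertex-enumeration
oracle on tiny models and (ii) cobrapy on the toy network.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from anaerodesign import synthetic
from anaerodesign.exceptions import (
    ConfigError,
    ModelValidationError,
    ParseError,
    PreconditionError,
)
from anaerodesign.fba import (
    GROWTH_EPS,
    LP_TOLERANCE,
    MetabolicModel,
    Medium,
    Reaction,
    blocked_biomass_precursors,
    fba,
    format_equation,
    load_model,
    parse_equation,
    propose_media_supplements,
    set_anoxic,
    trace_oxygen_dependencies,
    write_model,
    _effective_bounds,
)

DENIT = frozenset(synthetic.DENITRIFICATION_REACTIONS)


# --- independent oracle: vertex enumeration of the flux polytope ----------

def vertex_enumeration_optimum(model, medium, objective):
    """Max objective over vertices of {v : Sv=0, l<=v<=u} by brute force."""
    rids = list(model.reactions)
    met_idx = {m: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(rids)))
    for j, rid in enumerate(rids):
        for m, c in model.reactions[rid].stoich.items():
            S[met_idx[m], j] = c
    bounds = _effective_bounds(model, medium)
    lo = np.array([bounds[r][0] for r in rids])
    hi = np.array([bounds[r][1] for r in rids])
    obj_j = rids.index(objective)
    best = None
    n = len(rids)
    for fixed in itertools.product([None, "lo", "hi"], repeat=n):
        free = [j for j in range(n) if fixed[j] is None]
        v = np.where([f == "hi" for f in fixed], hi, lo).astype(float)
        if free:
            A = S[:, free]
            b = -S @ np.where([f is None for f in fixed], 0.0, v)
            sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < len(free):
                continue  # underdetermined: not a vertex
            v[free] = sol
        if np.max(np.abs(S @ v)) > 1e-7:
            continue
        if (v < lo - 1e-9).any() or (v > hi + 1e-9).any():
            continue
        if best is None or v[obj_j] > best:
            best = v[obj_j]
    return best


def random_tiny_model(rng):
    """<= 6 reactions: uptake -> chain of conversions -> objective sink."""
    n_met = int(rng.integers(1, 4))
    mets = [f"M{i}" for i in range(n_met)]
    reactions = {"EX_in": Reaction("EX_in", {"M0": -1.0}, -float(rng.integers(1, 10)), 1000.0)}
    for i in range(n_met - 1):
        coef = float(rng.integers(1, 3))
        reactions[f"R{i}"] = Reaction(f"R{i}", {mets[i]: -1.0, mets[i + 1]: coef}, 0.0, 1000.0)
    reactions["sink"] = Reaction("sink", {mets[-1]: -1.0}, 0.0, float(rng.integers(1, 50)))
    model = MetabolicModel(mets, reactions, objective="sink")
    medium = Medium(uptakes={"EX_in": -reactions["EX_in"].lower}, oxygen_exchange="EX_in")
    return model, medium


def test_lp_matches_vertex_enumeration_on_tiny_models():
    rng = np.random.default_rng(10)
    for _ in range(20):
        model, medium = random_tiny_model(rng)
        got = fba(model, medium).growth
        want = vertex_enumeration_optimum(model, medium, "sink")
        assert got == pytest.approx(want, abs=1e-7)


def test_toy_model_optimum_matches_cobra(toy_model, toy_medium):
    """cobrapy as an independent solver on the identical network."""
    import cobra

    cm = cobra.Model("toy")
    cm.add_metabolites([cobra.Metabolite(m) for m in toy_model.metabolites])
    bounds = _effective_bounds(toy_model, toy_medium)
    for rid, rxn in toy_model.reactions.items():
        cr = cobra.Reaction(rid)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in rxn.stoich.items()})
        cr.lower_bound, cr.upper_bound = bounds[rid]
    cm.objective = "biomass"
    expected = cm.optimize().objective_value
    assert fba(toy_model, toy_medium).growth == pytest.approx(expected, abs=1e-6)


# --- model container and format -------------------------------------------

class TestModelFormat:
    def test_equation_parse_and_format_round_trip(self):
        eq = "1 A + 2 B -> 1 C"
        st = parse_equation(eq)
        assert st == {"A": -1.0, "B": -2.0, "C": 1.0}
        assert parse_equation(format_equation(st)) == st

    def test_load_toy_table_round_trip(self, toy_model):
        text = write_model(toy_model)
        again = load_model(text)
        assert len(again.reactions) == len(toy_model.reactions)
        for rid, rxn in toy_model.reactions.items():
            assert again.reactions[rid].stoich == rxn.stoich
            assert again.reactions[rid].insertable == rxn.insertable
            assert again.reactions[rid].genes == rxn.genes

    def test_undeclared_metabolite_named_in_error(self):
        model = MetabolicModel(
            metabolites=["A"],
            reactions={"r": Reaction("r", {"A": -1.0, "X": 1.0})},
            objective="r",
        )
        with pytest.raises(ModelValidationError, match="X"):
            model.validate()

    def test_inverted_bounds_rejected(self):
        model = MetabolicModel(
            metabolites=["A"],
            reactions={"r": Reaction("r", {"A": -1.0}, lower=5.0, upper=1.0)},
            objective="r",
        )
        with pytest.raises(ModelValidationError, match="r"):
            model.validate()

    def test_missing_arrow_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_equation("1 A + 2 B")


# --- basic FBA behaviour ---------------------------------------------------

class TestFBA:
    def test_hand_solvable_chain(self):
        model = MetabolicModel(
            metabolites=["A"],
            reactions={
                "EX_A": Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
                "grow": Reaction("grow", {"A": -1.0}, 0.0, 1000.0),
            },
            objective="grow",
        )
        sol = fba(model, Medium(uptakes={"EX_A": 10.0}, oxygen_exchange="EX_A"))
        assert sol.growth == pytest.approx(10.0)

    def test_all_exchanges_closed_means_zero(self, toy_model):
        sol = fba(toy_model, Medium(uptakes={}, oxygen_exchange="EX_o2"))
        assert sol.growth == pytest.approx(0.0, abs=GROWTH_EPS)

    def test_optimal_solution_is_steady_and_within_bounds(self, toy_model, toy_medium):
        sol = fba(toy_model, toy_medium)
        rids = list(toy_model.reactions)
        met_idx = {m: i for i, m in enumerate(toy_model.metabolites)}
        S = np.zeros((len(toy_model.metabolites), len(rids)))
        for j, rid in enumerate(rids):
            for m, c in toy_model.reactions[rid].stoich.items():
                S[met_idx[m], j] = c
        v = sol.fluxes.loc[rids].to_numpy()
        assert np.max(np.abs(S @ v)) <= 1e-6
        bounds = _effective_bounds(toy_model, toy_medium)
        for rid in rids:
            lo, hi = bounds[rid]
            assert lo - LP_TOLERANCE <= sol.fluxes[rid] <= hi + LP_TOLERANCE

    def test_enlarging_uptake_never_decreases_growth(self, toy_model):
        prev = -1.0
        for glc in [0.0, 1.0, 3.0, 6.14, 20.0]:
            med = Medium(
                uptakes={"EX_glc": glc, "EX_o2": 1000.0, "EX_no3": 1000.0},
                oxygen_exchange="EX_o2",
            )
            g = fba(toy_model, med).growth
            assert g >= prev - 1e-9
            prev = g


class TestAnoxia:
    def test_set_anoxic_only_touches_oxygen(self, toy_medium):
        anox = set_anoxic(toy_medium)
        assert anox.uptakes["EX_o2"] == 0.0
        assert anox.uptakes["EX_glc"] == pytest.approx(6.14)
        assert set_anoxic(anox).uptakes == anox.uptakes  # idempotent

    def test_missing_oxygen_exchange(self):
        with pytest.raises(ConfigError):
            set_anoxic(Medium(uptakes={"EX_glc": 6.14}, oxygen_exchange="EX_o2"))

    def test_anoxic_growth_never_exceeds_aerobic(self, toy_model, toy_medium):
        aerobic = fba(toy_model, toy_medium).growth
        anoxic = fba(toy_model, set_anoxic(toy_medium)).growth
        assert anoxic <= aerobic + 1e-9


# --- gap analysis ----------------------------------------------------------

class TestGapAnalysis:
    def test_aerobic_nothing_blocked(self, toy_model, toy_medium):
        blocked = blocked_biomass_precursors(toy_model, toy_medium)
        assert not blocked["blocked"].any()

    def test_anoxic_blocked_set_is_the_cofactors(self, toy_model, toy_medium):
        anox = set_anoxic(toy_medium)
        blocked = blocked_biomass_precursors(toy_model, anox, enabled=DENIT)
        assert set(blocked.index[blocked["blocked"]]) == set(
            synthetic.COFACTOR_METABOLITES
        )

    def test_empty_biomass_gives_empty_result(self):
        model = MetabolicModel(
            metabolites=["A"],
            reactions={
                "EX_A": Reaction("EX_A", {"A": -1.0}, -1.0, 1000.0),
                "sinkA": Reaction("sinkA", {"A": -1.0}),
                "biomass": Reaction("biomass", {}),
            },
            objective="biomass",
        )
        res = blocked_biomass_precursors(model, Medium(uptakes={"EX_A": 1.0}, oxygen_exchange="EX_A"))
        assert res.empty

    def test_trace_reports_synthesis_relief_and_exchange(self, toy_model, toy_medium):
        anox = set_anoxic(toy_medium)
        tr = trace_oxygen_dependencies(toy_model, anox, "b12", enabled=DENIT)
        changes = set(zip(tr["change"], tr["reaction_id"]))
        assert ("relieve_oxygen", "B12S") in changes
        assert ("open_exchange", "EX_b12") in changes
        assert ("open_exchange", "EX_o2") not in changes
        genes = tr.loc[tr["reaction_id"] == "B12S", "genes"].iloc[0]
        assert "cobG" in genes

    def test_trace_requires_blocked_precursor(self, toy_model, toy_medium):
        with pytest.raises(PreconditionError):
            trace_oxygen_dependencies(toy_model, toy_medium, "b12")

    def test_minimal_supplement_set_is_the_three_vitamins(self, toy_model, toy_medium):
        anox = set_anoxic(toy_medium)
        minimal = propose_media_supplements(
            toy_model, anox, synthetic.VITAMIN_EXCHANGES, enabled=DENIT
        )
        assert minimal == [frozenset(synthetic.VITAMIN_EXCHANGES)]

    def test_no_supplement_works_without_denitrification(self, toy_model, toy_medium):
        anox = set_anoxic(toy_medium)
        assert propose_media_supplements(toy_model, anox, synthetic.VITAMIN_EXCHANGES) == []

    def test_supplement_preconditions(self, toy_model, toy_medium):
        with pytest.raises(PreconditionError):
            propose_media_supplements(toy_model, toy_medium, synthetic.VITAMIN_EXCHANGES)
        anox = set_anoxic(toy_medium)
        assert propose_media_supplements(toy_model, anox, []) == []
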