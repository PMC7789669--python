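"""Flux balance analysis and oxygen-gap tracing on metabolic models.

The model container is deliberately small: stoichiometric coefficient maps,
flux bounds in mmol gdw^-1 h^-1, gene labels, and an ``insertable`` flag on
reactions that are candidates for genomic insertion (e.g. a denitrification
pathway) and are therefore disabled unless explicitly enabled. FBA is the
linear program max c.v subject to S.v = 0 and bounds, solved with HiGHS.

Conventions: an *exchange* reaction is named ``EX_*`` and touches exactly
one metabolite with coefficient -1; negative exchange flux is uptake (other
single-metabolite reactions, e.g. an ATP-maintenance sink, are ordinary
internal reactions); a medium maps exchange IDs
to maximal uptake rates and sets exchange lower bounds to -uptake, closing
uptake through every exchange it does not mention.

The gap analysis asks which biomass precursors cannot be synthesized under a
medium (maximal demand flux <= GROWTH_EPS), which single relief — removing a
reaction's oxygen requirement, enabling an insertable reaction, or opening a
closed exchange — unblocks each, and which minimal exchange subsets restore
growth.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import ConfigError, ModelValidationError, ParseError, PreconditionError

GROWTH_EPS = 1e-6     # fluxes at or below this are "no growth" / "blocked"
LP_TOLERANCE = 1e-9   # steady-state and bound tolerance on optimal solutions
OPEN_UPTAKE = 10.0    # uptake rate used when probing a closed exchange


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]        # metabolite -> coefficient (<0 consumed)
    lower: float = 0.0
    upper: float = 1000.0
    genes: tuple[str, ...] = ()
    insertable: bool = False

    @property
    def is_exchange(self) -> bool:
        return (
            self.id.startswith("EX_")
            and len(self.stoich) == 1
            and next(iter(self.stoich.values())) < 0
        )


@dataclass
class MetabolicModel:
    metabolites: list[str]
    reactions: dict[str, Reaction]
    objective: str

    def validate(self) -> None:
        mets = set(self.metabolites)
        for rid, rxn in self.reactions.items():
            unknown = [m for m in rxn.stoich if m not in mets]
            if unknown:
                raise ModelValidationError(
                    f"reaction {rid!r} references undeclared metabolite(s): {unknown}"
                )
            if rxn.lower > rxn.upper:
                raise ModelValidationError(
                    f"reaction {rid!r} has lower bound {rxn.lower} > upper bound {rxn.upper}"
                )
        if self.objective not in self.reactions:
            raise ModelValidationError(f"objective reaction {self.objective!r} not in model")

    @property
    def exchanges(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if r.is_exchange]

    def biomass_substrates(self) -> list[str]:
        return [m for m, c in self.reactions[self.objective].stoich.items() if c < 0]


@dataclass(frozen=True)
class Medium:
    """Exchange ID -> maximal uptake rate (mmol gdw^-1 h^-1)."""

    uptakes: Mapping[str, float]
    oxygen_exchange: str = "EX_o2"

    def __post_init__(self) -> None:
        for ex, rate in self.uptakes.items():
            if rate < 0:
                raise ConfigError(f"uptake rate for {ex!r} must be >= 0, got {rate}")


def set_anoxic(medium: Medium) -> Medium:
    """Same medium with the oxygen uptake closed (idempotent)."""
    if medium.oxygen_exchange not in medium.uptakes:
        raise ConfigError(
            f"medium has no oxygen exchange entry {medium.oxygen_exchange!r}"
        )
    up = dict(medium.uptakes)
    up[medium.oxygen_exchange] = 0.0
    return replace(medium, uptakes=up)


@dataclass
class FluxSolution:
    status: str                 # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    fluxes: pd.Series | None

    @property
    def growth(self) -> float:
        # + 0.0 normalizes a -0.0 LP optimum
        return float(self.objective) + 0.0 if self.status == "optimal" else 0.0


def _effective_bounds(
    model: MetabolicModel,
    medium: Medium,
    enabled: frozenset[str] | set[str] = frozenset(),
) -> dict[str, tuple[float, float]]:
    bounds: dict[str, tuple[float, float]] = {}
    for rid, rxn in model.reactions.items():
        lo, hi = rxn.lower, rxn.upper
        if rxn.insertable and rid not in enabled:
            lo, hi = 0.0, 0.0
        if rxn.is_exchange:
            uptake = medium.uptakes.get(rid, 0.0)
            lo = -float(uptake)
            hi = max(hi, 0.0)
        bounds[rid] = (lo, hi)
    return bounds


def fba(
    model: MetabolicModel,
    medium: Medium,
    enabled: frozenset[str] | set[str] = frozenset(),
    objective: str | None = None,
) -> FluxSolution:
    """Maximize the objective flux at steady state under the medium."""
    model.validate()
    rids = list(model.reactions)
    met_idx = {m: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(rids)))
    for j, rid in enumerate(rids):
        for m, coef in model.reactions[rid].stoich.items():
            S[met_idx[m], j] = coef
    obj = objective or model.objective
    if obj not in model.reactions:
        raise ConfigError(f"objective reaction {obj!r} not in model")
    c = np.zeros(len(rids))
    c[rids.index(obj)] = -1.0  # linprog minimizes
    bounds = _effective_bounds(model, medium, enabled)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[bounds[r] for r in rids],
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective=None, fluxes=None)
    if res.status == 3:
        return FluxSolution(status="unbounded", objective=None, fluxes=None)
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = pd.Series(res.x, index=rids, name="flux")
    return FluxSolution(status="optimal", objective=float(-res.fun), fluxes=fluxes)


# ---------------------------------------------------------------------------
# tabular model format

_ARROWS = ("<=>", "<->", "->")


def _parse_side(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
        if not m:
            raise ParseError(f"cannot parse equation term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"1 A + 2 B -> 1 C"`` into a coefficient map (reactants < 0)."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise ParseError(f"equation {equation!r} lacks an arrow (-> or <=>)")
    stoich: dict[str, float] = {}
    for met, coef in _parse_side(left).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(right).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_equation(stoich: Mapping[str, float]) -> str:
    def side(items: Iterable[tuple[str, float]]) -> str:
        return " + ".join(f"{c:g} {m}" for m, c in items)

    left = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    right = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    return f"{side(left)} -> {side(right)}"


MODEL_COLUMNS = ("reaction_id", "equation", "lower", "upper", "genes", "flags")


def load_model(source: str | IO[str], objective: str = "biomass") -> MetabolicModel:
    """Load a model from the tab-separated reaction table (or SBML).

    The table has columns ``reaction_id equation lower upper genes flags``;
    ``genes`` is comma-separated (may be empty), ``flags`` may contain
    ``insertable``. A string argument ending in ``.xml`` or ``.sbml`` is
    treated as an SBML path and read through cobrapy.
    """
    if isinstance(source, str) and source.endswith((".xml", ".sbml")):
        return load_sbml(source)
    import io as _io

    if isinstance(source, str):
        source = _io.StringIO(source)
    header = source.readline().rstrip("\n").split("\t")
    missing = [c for c in MODEL_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"model header missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in MODEL_COLUMNS}
    reactions: dict[str, Reaction] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        try:
            rid = f[idx["reaction_id"]]
            stoich = parse_equation(f[idx["equation"]])
            lo, hi = float(f[idx["lower"]]), float(f[idx["upper"]])
            genes = tuple(g for g in f[idx["genes"]].split(",") if g)
            insertable = "insertable" in f[idx["flags"]]
        except (IndexError, ValueError, ParseError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        reactions[rid] = Reaction(
            id=rid, stoich=stoich, lower=lo, upper=hi, genes=genes, insertable=insertable
        )
    metabolites = sorted({m for r in reactions.values() for m in r.stoich})
    model = MetabolicModel(metabolites=metabolites, reactions=reactions, objective=objective)
    model.validate()
    return model


def write_model(model: MetabolicModel) -> str:
    """Serialize to the tabular reaction format (round-trips exactly)."""
    lines = ["\t".join(MODEL_COLUMNS)]
    for rid, r in model.reactions.items():
        flags = "insertable" if r.insertable else ""
        lines.append(
            f"{rid}\t{format_equation(r.stoich)}\t{r.lower:g}\t{r.upper:g}\t"
            f"{','.join(r.genes)}\t{flags}"
        )
    return "\n".join(lines) + "\n"


def load_sbml(path: str) -> MetabolicModel:
    """Import an SBML model via cobrapy into the package container."""
    from cobra.io import read_sbml_model

    cm = read_sbml_model(path)
    reactions: dict[str, Reaction] = {}
    for rxn in cm.reactions:
        reactions[rxn.id] = Reaction(
            id=rxn.id,
            stoich={m.id: c for m, c in rxn.metabolites.items()},
            lower=rxn.lower_bound,
            upper=rxn.upper_bound,
            genes=tuple(g.id for g in rxn.genes),
        )
    objective = None
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    if objective is None:
        raise ModelValidationError("SBML model has no objective reaction")
    model = MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        objective=objective,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# gap analysis


def _with_demand(model: MetabolicModel, metabolite: str) -> tuple[MetabolicModel, str]:
    """Copy of the model with biomass disabled and a demand on ``metabolite``."""
    demand_id = f"DM_{metabolite}"
    reactions = dict(model.reactions)
    bio = reactions[model.objective]
    reactions[model.objective] = replace(bio, lower=0.0, upper=0.0)
    reactions[demand_id] = Reaction(id=demand_id, stoich={metabolite: -1.0}, lower=0.0, upper=1000.0)
    m2 = MetabolicModel(
        metabolites=list(model.metabolites), reactions=reactions, objective=demand_id
    )
    return m2, demand_id


def max_synthesis(
    model: MetabolicModel,
    medium: Medium,
    metabolite: str,
    enabled: frozenset[str] | set[str] = frozenset(),
) -> float:
    """Maximal steady-state production flux of one metabolite (demand FBA)."""
    m2, demand = _with_demand(model, metabolite)
    sol = fba(m2, medium, enabled=enabled, objective=demand)
    return sol.growth


def blocked_biomass_precursors(
    model: MetabolicModel,
    medium: Medium,
    enabled: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Per biomass substrate: maximal synthesis flux and blocked flag."""
    rows = []
    for met in model.biomass_substrates():
        v = max_synthesis(model, medium, met, enabled=enabled)
        rows.append((met, v, v <= GROWTH_EPS))
    return pd.DataFrame(rows, columns=["metabolite", "max_flux", "blocked"]).set_index(
        "metabolite"
    )


def _without_oxygen(rxn: Reaction, oxygen: str) -> Reaction:
    stoich = {m: c for m, c in rxn.stoich.items() if m != oxygen}
    return replace(rxn, stoich=stoich)


def trace_oxygen_dependencies(
    model: MetabolicModel,
    medium: Medium,
    precursor: str,
    enabled: frozenset[str] | set[str] = frozenset(),
    oxygen_metabolite: str = "o2",
) -> pd.DataFrame:
    """Single reliefs that unblock a blocked precursor, with gene labels.

    Tests, one change at a time: (i) each oxygen-consuming internal reaction
    with its oxygen requirement removed, (ii) each disabled insertable
    reaction enabled, and (iii) each closed exchange opened. Returns every
    change raising the precursor's maximal synthesis above GROWTH_EPS.
    """
    if max_synthesis(model, medium, precursor, enabled=enabled) > GROWTH_EPS:
        raise PreconditionError(
            f"precursor {precursor!r} is not blocked under the given medium"
        )
    reliefs: list[tuple[str, str, str, float]] = []

    def probe(m: MetabolicModel, med: Medium, en: frozenset[str]) -> float:
        return max_synthesis(m, med, precursor, enabled=en)

    en = frozenset(enabled)
    # (i) relieve oxygen requirements
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange or rxn.stoich.get(oxygen_metabolite, 0.0) >= 0.0:
            continue
        reactions = dict(model.reactions)
        reactions[rid] = _without_oxygen(rxn, oxygen_metabolite)
        m2 = MetabolicModel(list(model.metabolites), reactions, model.objective)
        v = probe(m2, medium, en)
        if v > GROWTH_EPS:
            reliefs.append(("relieve_oxygen", rid, ",".join(rxn.genes), v))
    # (ii) enable insertables
    for rid, rxn in model.reactions.items():
        if rxn.insertable and rid not in en:
            v = probe(model, medium, en | {rid})
            if v > GROWTH_EPS:
                reliefs.append(("enable_insertable", rid, ",".join(rxn.genes), v))
    # (iii) open closed exchanges (never the oxygen exchange itself: the
    # question is what relieves the block *without* restoring oxygen)
    for rid in model.exchanges:
        if medium.uptakes.get(rid, 0.0) > 0.0 or rid == medium.oxygen_exchange:
            continue
        med2 = replace(medium, uptakes={**medium.uptakes, rid: OPEN_UPTAKE})
        v = probe(model, med2, en)
        if v > GROWTH_EPS:
            reliefs.append(("open_exchange", rid, ",".join(model.reactions[rid].genes), v))
    return pd.DataFrame(
        reliefs, columns=["change", "reaction_id", "genes", "max_flux"]
    )


def propose_media_supplements(
    model: MetabolicModel,
    medium: Medium,
    candidates: Iterable[str],
    enabled: frozenset[str] | set[str] = frozenset(),
    max_size: int = 4,
) -> list[frozenset[str]]:
    """Minimal candidate-exchange subsets whose opening restores growth.

    Enumerates subsets in increasing size (exhaustive up to ``max_size``);
    supersets of a working subset are never reported.
    """
    candidates = sorted(set(candidates))
    if fba(model, medium, enabled=enabled).growth > GROWTH_EPS:
        raise PreconditionError("medium already supports growth; nothing to supplement")
    minimal: list[frozenset[str]] = []
    for size in range(1, min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            s = frozenset(combo)
            if any(prev <= s for prev in minimal):
                continue
            med2 = replace(
                medium, uptakes={**medium.uptakes, **{ex: OPEN_UPTAKE for ex in combo}}
            )
            if fba(model, med2, enabled=enabled).growth > GROWTH_EPS:
                minimal.append(s)
    return minimal
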