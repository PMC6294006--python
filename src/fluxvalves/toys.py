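"""Small synthetic networks with known ground truth, plus a brute-force oracle.

The toys are hand-built so that every LP solves in milliseconds and the
complete intervention lattice can be enumerated exhaustively, giving an
independent reference against which the dual MILP is checked.  Each toy
carries a non-carbon energy cofactor ``E`` consumed by a maintenance
reaction, so the desired production region genuinely excludes the zero flux
vector (maintenance demand must be met while producing).

Topology tags
-------------
two_branch
    Substrate splits into independent biomass and product branches; a
    single valve on the biomass branch decouples the states.
bypass
    The product can also be made through a carbon-lossy bypass that must be
    statically knocked out, in addition to the biomass-branch valve.
shared_intermediate
    Biomass requires an overflow metabolite whose export leaks carbon; the
    export is a static knockout that primes the biomass-branch valve.
reversible_loop
    The biomass branch passes through a reversible interconversion, so
    intervening on it exercises the signed (zp/zn) dual indicator pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import MetabolicModel, Metabolite, Reaction
from .scenario import DecouplingSpec, LinearRegion
from . import validation


@dataclass
class ToyNetwork:
    model: MetabolicModel
    spec: DecouplingSpec
    tag: str


def _mk(mid, formula):
    return Metabolite(id=mid, formula=formula, compartment="c")


def _rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem=""):
    return Reaction(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        subsystem=subsystem,
    )


def make_toy(tag: str) -> ToyNetwork:
    """Deterministic toy network for the given topology tag."""
    S = _mk("S", {"C": 6})
    P = _mk("P", {"C": 3})
    B = _mk("B", {"C": 6})
    E = _mk("E", {})  # energy cofactor, non-carbon

    if tag == "two_branch":
        mets = [S, B, P, E]
        rxns = [
            _rxn("EX_S", {"S": 1.0}, 0, 10, "exchange"),
            _rxn("RB", {"S": -1.0, "B": 1.0, "E": 1.0}, subsystem="biomass_branch"),
            _rxn("EX_B", {"B": -1.0}, subsystem="exchange"),
            _rxn("RP", {"S": -1.0, "P": 1.0, "E": 1.0}, subsystem="product_branch"),
            _rxn("EX_P", {"P": -1.0}, subsystem="exchange"),
            _rxn("ATPM", {"E": -1.0}, subsystem="maintenance"),
        ]
    elif tag == "bypass":
        mets = [S, B, P, E]
        rxns = [
            _rxn("EX_S", {"S": 1.0}, 0, 10, "exchange"),
            _rxn("RB", {"S": -1.0, "B": 1.0, "E": 1.0}, subsystem="biomass_branch"),
            _rxn("EX_B", {"B": -1.0}, subsystem="exchange"),
            _rxn("RP1", {"S": -1.0, "P": 1.0, "E": 1.0}, subsystem="product_branch"),
            _rxn("RP2", {"S": -1.0, "P": 0.5, "E": 1.0}, subsystem="bypass"),
            _rxn("EX_P", {"P": -1.0}, subsystem="exchange"),
            _rxn("ATPM", {"E": -1.0}, subsystem="maintenance"),
        ]
    elif tag == "shared_intermediate":
        M = _mk("M", {"C": 6})
        O = _mk("O", {"C": 3})
        mets = [S, M, O, B, P, E]
        rxns = [
            _rxn("EX_S", {"S": 1.0}, 0, 10, "exchange"),
            _rxn("RM", {"S": -1.0, "M": 1.0, "E": 1.0}, subsystem="upper"),
            _rxn("RO", {"M": -1.0, "O": 1.0}, subsystem="overflow"),
            _rxn("RB", {"M": -1.0, "O": -1.0, "B": 2.0}, subsystem="biomass_branch"),
            _rxn("EX_B", {"B": -1.0}, subsystem="exchange"),
            _rxn("EX_O", {"O": -1.0}, subsystem="exchange"),
            _rxn("RP", {"M": -1.0, "P": 1.0, "E": 1.0}, subsystem="product_branch"),
            _rxn("EX_P", {"P": -1.0}, subsystem="exchange"),
            _rxn("ATPM", {"E": -1.0}, subsystem="maintenance"),
        ]
    elif tag == "reversible_loop":
        A = _mk("A", {"C": 6})
        Bi = _mk("Bi", {"C": 6})
        mets = [S, A, Bi, B, P, E]
        rxns = [
            _rxn("EX_S", {"S": 1.0}, 0, 10, "exchange"),
            _rxn("RA", {"S": -1.0, "A": 1.0, "E": 1.0}, subsystem="upper"),
            _rxn("RAB", {"A": -1.0, "Bi": 1.0}, lb=-1000, subsystem="loop"),
            _rxn("RB", {"Bi": -1.0, "B": 1.0}, subsystem="biomass_branch"),
            _rxn("EX_B", {"B": -1.0}, subsystem="exchange"),
            _rxn("RP", {"A": -1.0, "P": 1.0, "E": 1.0}, subsystem="product_branch"),
            _rxn("EX_P", {"P": -1.0}, subsystem="exchange"),
            _rxn("ATPM", {"E": -1.0}, subsystem="maintenance"),
        ]
    else:
        raise ValueError(f"unknown toy tag: {tag!r}")

    model = MetabolicModel(id=f"toy_{tag}", metabolites=mets, reactions=rxns)
    assert model.n <= 12
    spec = DecouplingSpec(
        product_rxn="EX_P",
        substrate_rxn="EX_S",
        biomass_rxn="EX_B",
        atpm_rxn="ATPM",
        mode="full",
        min_product_fraction=0.9,
        min_biomass_fraction_state1=0.9,
        uptake_max=10.0,
        atpm_min=1.0,
    )
    model.roles["substrate"] = "EX_S"
    model.roles["atpm"] = "ATPM"
    return ToyNetwork(model=model, spec=spec, tag=tag)


ALL_TAGS = ("two_branch", "bypass", "shared_intermediate", "reversible_loop")


@dataclass
class OracleResult:
    """Exhaustive ground truth: all set-minimal valid (knockout, valve) designs."""

    minimal_strategies: frozenset[tuple[frozenset[str], frozenset[str]]]
    min_objective: int  # -1 when no valid design exists within the size bound

    @property
    def minimal_supports(self) -> frozenset[frozenset[str]]:
        return frozenset(ko | va for ko, va in self.minimal_strategies)


def brute_force(
    model: MetabolicModel,
    regions: tuple[LinearRegion, LinearRegion, LinearRegion],
    max_size: int,
    max_valves: int,
    candidates: list[str] | None = None,
    valve_count_mode: str = "le",
    guard: int = 200_000,
) -> OracleResult:
    """Enumerate all intervention designs up to ``max_size`` by LP checking.

    Supports are enumerated in increasing cardinality; supersets of already
    accepted supports are pruned (set-minimality).  For each surviving
    support every valve sub-assignment within the budget is checked with
    the independent LP verifier.  ``candidates`` restricts the reactions
    eligible for intervention (pass the same blacklist-complement the MILP
    uses to make the comparison meaningful).
    """
    undesired, desired_prod, desired_growth = regions
    if candidates is None:
        candidates = [r.id for r in model.reactions]
    total = sum(
        1
        for k in range(1, max_size + 1)
        for _ in itertools.combinations(range(len(candidates)), k)
    )
    if total > guard:
        raise ValueError(f"enumeration of {total} supports exceeds guard {guard}")

    accepted: list[tuple[frozenset[str], frozenset[str]]] = []
    minimal_supports: list[frozenset[str]] = []
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(sorted(candidates), k):
            support = frozenset(combo)
            if any(s <= support for s in minimal_supports):
                continue
            if not validation.undesired_region_eliminated(model, support, undesired):
                continue
            if not validation.production_state_feasible(
                model, support, desired_prod
            ):
                continue
            found = []
            max_v = min(max_valves, k)
            sizes = (
                range(max_v, max_v + 1)
                if valve_count_mode == "eq"
                else range(0, max_v + 1)
            )
            for nv in sizes:
                for valve_combo in itertools.combinations(sorted(support), nv):
                    valves = frozenset(valve_combo)
                    kos = support - valves
                    if validation.growth_state_feasible(model, kos, desired_growth):
                        found.append((kos, valves))
            if found:
                minimal_supports.append(support)
                accepted.extend(found)
    if not accepted:
        return OracleResult(frozenset(), -1)
    min_obj = min(len(ko | va) for ko, va in accepted)
    return OracleResult(frozenset(accepted), min_obj)


def default_candidates(toy: ToyNetwork) -> list[str]:
    """Intervention candidates mirroring the MILP's default role blacklist."""
    blocked = toy.spec.role_ids()
    return [r.id for r in toy.model.reactions if r.id not in blocked]
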