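"""Target-product selection and essentiality blacklists.

Candidate products for decoupling designs are drawn from the model's export
(exchange) reactions: a target must be *organic* (its metabolite's formula
contains carbon and is not one of the classic small inorganics) and
*producible* from the configured substrate (positive maximum export flux by
flux variability analysis).

Reactions essential for growth can be blacklisted from serving as valves in
partial-decoupling designs, either computed here by an exhaustive
single-closure FBA screen or supplied as an experimentally determined list
(one reaction id per line).  The computed screen is a model-based
approximation of experimental essentiality and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    MetabolicModel,
    PRODUCIBILITY_TOL,
    exchange_coefficient,
    fba,
    fva_max,
)

#: Carbon-containing species conventionally treated as inorganic, as
#: elemental composition signatures: CO2, bicarbonate, carbon monoxide,
#: cyanide.  Configurable at call time.
DEFAULT_INORGANIC_FORMULAS: tuple[frozenset, ...] = (
    frozenset({("C", 1), ("O", 2)}),            # CO2
    frozenset({("C", 1), ("H", 1), ("O", 3)}),  # HCO3-
    frozenset({("C", 1), ("O", 1)}),            # CO
    frozenset({("C", 1), ("N", 1)}),            # CN-
)


@dataclass
class TargetList:
    targets: list[str]
    rationale: dict[str, dict] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["exchange\torganic\tproducible\tmax_flux"]
        for rid, info in sorted(self.rationale.items()):
            lines.append(
                f"{rid}\t{info['organic']}\t{info['producible']}\t"
                f"{'' if info['max_flux'] is None else format(info['max_flux'], '.6g')}"
            )
        return "\n".join(lines) + "\n"


def is_organic(
    formula: dict[str, int],
    inorganic_formulas: tuple[frozenset, ...] = DEFAULT_INORGANIC_FORMULAS,
) -> bool:
    if formula.get("C", 0) < 1:
        return False
    signature = frozenset((el, int(cnt)) for el, cnt in formula.items() if cnt)
    return signature not in inorganic_formulas


def select_targets(
    model: MetabolicModel,
    substrate: str,
    inorganic_formulas: tuple[frozenset, ...] = DEFAULT_INORGANIC_FORMULAS,
) -> TargetList:
    """Organic, producible export reactions under the configured medium.

    The rationale table records every non-substrate exchange: whether its
    metabolite passed the organic rule and, for organic ones, its maximum
    export flux (producibility is evaluated on the model as given, before
    any tractability pruning).
    """
    met_by_id = {m.id: m for m in model.metabolites}
    organic_exchanges = []
    rationale: dict[str, dict] = {}
    for rxn in model.reactions:
        if not rxn.is_exchange or rxn.id == substrate:
            continue
        mid = next(iter(rxn.stoichiometry))
        organic = is_organic(met_by_id[mid].formula, inorganic_formulas)
        rationale[rxn.id] = {"organic": organic, "producible": False, "max_flux": None}
        if organic:
            organic_exchanges.append(rxn.id)
    # Export rate of an exchange with coefficient c is -c * v: for the BiGG
    # convention (c = -1) the FVA flux maximum is the export maximum; for a
    # source-style exchange (c > 0) export is the reverse direction.
    bigg_style = [r for r in organic_exchanges if exchange_coefficient(model, r) < 0]
    maxima = fva_max(model, bigg_style)
    targets = []
    for rid in organic_exchanges:
        c = exchange_coefficient(model, rid)
        if c < 0:
            export_max = -c * maxima[rid]
        else:
            vmin, _ = fba(model, rid, maximize=False)
            export_max = -c * vmin
        rationale[rid]["max_flux"] = export_max
        if export_max > PRODUCIBILITY_TOL:
            rationale[rid]["producible"] = True
            targets.append(rid)
    return TargetList(targets=targets, rationale=rationale)


def essential_reaction_blacklist(
    model: MetabolicModel,
    biomass_rxn: str,
    source: str = "computed",
    min_growth: float = 0.1,
    path=None,
    candidates: list[str] | None = None,
) -> frozenset[str]:
    """Reactions that cannot be valves when growth must persist.

    ``computed`` mode closes each reaction singly and marks it essential
    when the maximum biomass flux drops below ``min_growth`` (default the
    partial-decoupling production-state growth floor, h^-1).  This is a
    model-derived approximation of an experimental essentiality screen.
    ``provided-list`` mode reads one reaction id per line from ``path``.
    """
    if source == "provided-list":
        if path is None:
            raise ValueError("provided-list mode requires a file path")
        with open(path) as fh:
            ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        for rid in ids:
            model.reaction(rid)
        return frozenset(ids)
    if source != "computed":
        raise ValueError(f"unknown essentiality source {source!r}")
    if candidates is None:
        candidates = [r.id for r in model.reactions]
    essential = set()
    probe = model.copy()
    for rid in candidates:
        rxn = probe.reaction(rid)
        lb0, ub0 = rxn.lower_bound, rxn.upper_bound
        if lb0 > 0 or ub0 < 0:
            # the model demands flux here (e.g. ATP maintenance); carrying
            # none is infeasible by definition
            essential.add(rid)
            continue
        rxn.lower_bound = rxn.upper_bound = 0.0
        try:
            growth, _ = fba(probe, biomass_rxn)
        except Exception:
            growth = 0.0
        if growth < min_growth:
            essential.add(rid)
        rxn.lower_bound, rxn.upper_bound = lb0, ub0
    return frozenset(essential)
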