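"""Independent LP-only verification of intervention strategies.

Every strategy returned by the MILP is re-checked here with plain linear
programs that never consult the MILP's own dual certificate:

* *undesired eliminated* — the homogeneous production-state system
  ``{N v = 0, v_i >= 0 for irreversible i, T v <= t}`` with every
  intervened reaction (knockouts and valves, both directions) fixed to
  zero must be LP-infeasible.  This is exactly the primal system whose
  Farkas dual the MILP solves, so certificate agreement is two-sided.
* *desired production feasible* — the bounded production state (model
  bounds, interventions closed, D rows) admits a flux vector.
* *desired growth feasible* — the bounded growth state (knockouts closed,
  valves open, G rows) admits a flux vector.

The report also quantifies the achieved guarantees: the LP minimum of the
product yield at full substrate uptake in the production state, and the LP
maximum biomass yield in the growth state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, exchange_coefficient, reaction_rate_coefficients
from .scenario import DecouplingSpec, LinearRegion
from .milp import InterventionStrategy
import json


@dataclass
class ValidationReport:
    undesired_eliminated: bool
    desired_prod_feasible: bool
    desired_growth_feasible: bool
    guaranteed_min_product_yield: float | None = None
    max_growth_state_biomass_yield: float | None = None
    minimal: bool | None = None

    @property
    def valid(self) -> bool:
        return (
            self.undesired_eliminated
            and self.desired_prod_feasible
            and self.desired_growth_feasible
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["valid"] = self.valid
        return json.dumps(d, indent=2, sort_keys=True)


def _closed_bounds(model, closed, lb, ub):
    lb, ub = lb.copy(), ub.copy()
    for rid in closed:
        j = model.reaction_index(rid)
        lb[j] = ub[j] = 0.0
    return lb, ub


def _feasible(A_ub, b_ub, A_eq, b_eq, lb, ub) -> bool:
    res = linprog(
        np.zeros(len(lb)),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res.status == 0


def undesired_region_eliminated(
    model: MetabolicModel, closed: frozenset[str], undesired: LinearRegion
) -> bool:
    """LP-infeasibility of the homogeneous undesired system with cuts closed."""
    n = model.n
    lb = np.where(
        np.array([r.reversible for r in model.reactions]), -np.inf, 0.0
    )
    ub = np.full(n, np.inf)
    lb2, ub2 = lb.copy(), ub.copy()
    for rid in closed:
        j = model.reaction_index(rid)
        lb2[j] = ub2[j] = 0.0
    return not _feasible(
        undesired.matrix,
        undesired.rhs,
        model.N,
        np.zeros(model.m),
        lb2,
        ub2,
    )


def production_state_feasible(
    model: MetabolicModel, closed: frozenset[str], desired_prod: LinearRegion
) -> bool:
    lb, ub = model.bounds_arrays()
    lb, ub = _closed_bounds(model, closed, lb, ub)
    return _feasible(
        desired_prod.matrix, desired_prod.rhs, model.N, np.zeros(model.m), lb, ub
    )


def growth_state_feasible(
    model: MetabolicModel, knockouts: frozenset[str], desired_growth: LinearRegion
) -> bool:
    lb, ub = model.bounds_arrays()
    lb, ub = _closed_bounds(model, knockouts, lb, ub)
    return _feasible(
        desired_growth.matrix, desired_growth.rhs, model.N, np.zeros(model.m), lb, ub
    )


def guaranteed_min_product_yield(
    model: MetabolicModel, closed: frozenset[str], spec: DecouplingSpec
) -> float | None:
    """Worst-case product yield at full uptake with interventions closed.

    Minimizes the product rate over all steady-state fluxes respecting the
    model bounds (ATP maintenance included) with substrate uptake fixed at
    ``r_S,max``; returns None when that system is infeasible (the strain
    cannot run at full uptake at all).  The D yield rows are deliberately
    *not* imposed — the point is what the stoichiometry alone guarantees.
    """
    lb, ub = model.bounds_arrays()
    lb, ub = _closed_bounds(model, closed, lb, ub)
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    lb[js] = ub[js] = spec.uptake_max / c_s
    jp, sp = reaction_rate_coefficients(model, spec.product_rxn, spec.substrate_rxn)
    c = np.zeros(model.n)
    c[jp] = sp  # minimize product rate
    res = linprog(
        c,
        A_eq=model.N,
        b_eq=np.zeros(model.m),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0:
        return None
    return float(sp * res.x[jp] / spec.uptake_max)


def max_product_yield(
    model: MetabolicModel, closed: frozenset[str], spec: DecouplingSpec
) -> float | None:
    """Best-case product yield at full uptake with interventions closed."""
    lb, ub = model.bounds_arrays()
    lb, ub = _closed_bounds(model, closed, lb, ub)
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    lb[js] = ub[js] = spec.uptake_max / c_s
    jp, sp = reaction_rate_coefficients(model, spec.product_rxn, spec.substrate_rxn)
    c = np.zeros(model.n)
    c[jp] = -sp
    res = linprog(
        c, A_eq=model.N, b_eq=np.zeros(model.m),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    if res.status != 0:
        return None
    return float(sp * res.x[jp] / spec.uptake_max)


def max_growth_biomass_yield(
    model: MetabolicModel, knockouts: frozenset[str], spec: DecouplingSpec
) -> float | None:
    """Maximum growth-state biomass yield (per r_S,max) with knockouts closed."""
    lb, ub = model.bounds_arrays()
    lb, ub = _closed_bounds(model, knockouts, lb, ub)
    jb, sb = reaction_rate_coefficients(model, spec.biomass_rxn, spec.substrate_rxn)
    c = np.zeros(model.n)
    c[jb] = -sb
    res = linprog(
        c, A_eq=model.N, b_eq=np.zeros(model.m),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    if res.status != 0:
        return None
    return float(sb * res.x[jb] / spec.uptake_max)


def verify_strategy(
    model: MetabolicModel,
    strategy: InterventionStrategy,
    regions: tuple[LinearRegion, LinearRegion, LinearRegion],
    spec: DecouplingSpec | None = None,
    check_minimal: bool = False,
) -> ValidationReport:
    """Full LP certificate for a strategy against the three regions.

    "Closed" in the production state means both directions of every
    intervened reaction (valves included); the growth state closes only
    the static knockouts.
    """
    undesired, desired_prod, desired_growth = regions
    closed = strategy.interventions
    report = ValidationReport(
        undesired_eliminated=undesired_region_eliminated(model, closed, undesired),
        desired_prod_feasible=production_state_feasible(model, closed, desired_prod),
        desired_growth_feasible=growth_state_feasible(
            model, strategy.knockouts, desired_growth
        ),
    )
    if spec is not None:
        report.guaranteed_min_product_yield = guaranteed_min_product_yield(
            model, closed, spec
        )
        report.max_growth_state_biomass_yield = max_growth_biomass_yield(
            model, strategy.knockouts, spec
        )
    if check_minimal and report.valid:
        report.minimal = check_minimality(model, strategy, regions)
    return report


def check_minimality(
    model: MetabolicModel,
    strategy: InterventionStrategy,
    regions: tuple[LinearRegion, LinearRegion, LinearRegion],
) -> bool:
    """Set-minimality: reopening any single intervention breaks validity.

    Reopening can only enlarge the desired feasible sets, so the decisive
    test for each intervention is whether the undesired region stays
    eliminated without it; if it does, that intervention was redundant.
    """
    undesired = regions[0]
    for rid in strategy.interventions:
        reduced = strategy.interventions - {rid}
        if undesired_region_eliminated(model, reduced, undesired):
            return False
    return True
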