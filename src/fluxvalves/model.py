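"""Constraint-based metabolic model container and baseline LP computations.

The model is a thin, explicit representation of a stoichiometric network:
an ordered list of metabolites (rows of the stoichiometric matrix ``N``) and
reactions (columns, each with flux bounds).  File I/O goes through cobrapy
(SBML Level 3 + fbc, BiGG-style JSON); all linear programming (FBA, FVA,
theoretical yields) is done here directly with scipy's HiGHS ``linprog`` so
that results are reproducible and independent of any global solver state.

Sign conventions
----------------
Exchange reactions touch exactly one metabolite.  For an exchange reaction
with stoichiometric coefficient ``c`` on its metabolite, a flux ``v`` adds
``c * v`` units of that metabolite to the network.  Substrate *uptake rate*
is therefore ``c_S * v_S`` (positive when importing; for the BiGG convention
``c_S = -1`` and uptake flux is negative).  Product export and biomass rates
are measured in the forward/positive direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: LP feasibility tolerance used to judge steady-state residuals and witnesses.
FEASIBILITY_TOL = 1e-9
#: Minimum flux treated as genuine producibility (above numerical noise).
PRODUCIBILITY_TOL = 1e-6
#: Replacement magnitude for infinite flux bounds (BiGG convention).
DEFAULT_INF = 1000.0


class ModelFormatError(ValueError):
    """A model file could not be parsed under the requested standard."""


class UnknownReactionError(KeyError):
    """A reaction id was looked up that does not exist in the model."""


class InfeasibleModelError(RuntimeError):
    """An LP on the model was infeasible; carries the solver status."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    compartment: str = ""


@dataclass
class Reaction:
    """A reaction column: stoichiometry (metabolite id -> coefficient) and bounds.

    A reaction is irreversible iff ``lower_bound >= 0``; an exchange iff its
    stoichiometry touches exactly one metabolite (boundary convention).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""
    subsystem: str = ""
    gene_association: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    """Ordered metabolites/reactions plus the sparse stoichiometric matrix.

    The matrix and index partitions are derived properties recomputed on
    demand, so structural edits (removing reactions, changing bounds) can be
    done by constructing a new instance without bookkeeping hazards.
    """

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    #: reaction ids protected from removal (set by :func:`configure_medium`)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelFormatError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelFormatError("duplicate reaction ids")

    # -- indexing -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def m(self) -> int:
        return len(self.metabolites)

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise UnknownReactionError(f"unknown reaction id: {rid!r}") from None

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise UnknownReactionError(f"unknown reaction id: {rid!r}") from None

    @property
    def N(self) -> sparse.csc_matrix:
        """Sparse m x n stoichiometric matrix."""
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                if not math.isfinite(coef):
                    raise ModelFormatError(
                        f"non-finite stoichiometric coefficient in {rxn.id}"
                    )
                rows.append(self._met_index[mid])
                cols.append(j)
                data.append(float(coef))
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(self.m, self.n), dtype=float
        )

    @property
    def irr_index(self) -> np.ndarray:
        return np.array(
            [j for j, r in enumerate(self.reactions) if not r.reversible], dtype=int
        )

    @property
    def rev_index(self) -> np.ndarray:
        return np.array(
            [j for j, r in enumerate(self.reactions) if r.reversible], dtype=int
        )

    def bounds_arrays(self, clip: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors, infinities clipped to ±DEFAULT_INF."""
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        if clip:
            lb = np.maximum(lb, -DEFAULT_INF)
            ub = np.minimum(ub, DEFAULT_INF)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m, formula=dict(m.formula)) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            roles=dict(self.roles),
        )


# ---------------------------------------------------------------------------
# I/O via cobrapy
# ---------------------------------------------------------------------------

def _from_cobra(cb) -> MetabolicModel:
    mets = []
    for m in cb.metabolites:
        try:
            formula = dict(m.elements) if m.formula else {}
        except Exception as exc:  # malformed formula string
            raise ModelFormatError(f"malformed formula on metabolite {m.id}") from exc
        mets.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                formula=formula,
                compartment=m.compartment or "",
            )
        )
    rxns = []
    for r in cb.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={met.id: float(c) for met, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
                subsystem=getattr(r, "subsystem", "") or "",
                gene_association=r.gene_reaction_rule or "",
            )
        )
    return MetabolicModel(id=cb.id or "model", metabolites=mets, reactions=rxns)


def _to_cobra(model: MetabolicModel):
    import cobra

    cb = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or None
        )
        if m.formula:
            cm.formula = "".join(
                f"{el}{int(cnt) if float(cnt).is_integer() else cnt}"
                for el, cnt in sorted(m.formula.items())
            )
        cmets[m.id] = cm
    cb.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cb.add_reactions(crxns)
    for r in model.reactions:
        cb.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: c for mid, c in r.stoichiometry.items()}
        )
        if r.gene_association:
            cb.reactions.get_by_id(r.id).gene_reaction_rule = r.gene_association
    return cb


def read_model(path, format: str = "auto") -> MetabolicModel:
    """Read an SBML (L3 + fbc) or BiGG-style JSON model file.

    ``format='auto'`` dispatches on suffix (.json vs .xml/.sbml, optionally
    .gz).  Parse failures raise :class:`ModelFormatError` naming the file.
    """
    import cobra.io

    path = str(path)
    if format == "auto":
        stem = path[:-3] if path.endswith(".gz") else path
        format = "bigg_json" if stem.endswith(".json") else "sbml"
    try:
        if format == "bigg_json":
            cb = cobra.io.load_json_model(path)
        elif format == "sbml":
            cb = cobra.io.read_sbml_model(path)
        else:
            raise ValueError(f"unknown model format: {format!r}")
    except ValueError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return _from_cobra(cb)


def write_model(model: MetabolicModel, path) -> None:
    """Write the model back out in BiGG JSON dialect."""
    import cobra.io

    cobra.io.save_json_model(_to_cobra(model), str(path))


def load_example_model(name: str = "e_coli_core") -> MetabolicModel:
    """Load a bundled reference model from cobrapy's installed data directory.

    ``e_coli_core`` (the BiGG core reconstruction of *E. coli* central
    metabolism, 72 metabolites / 95 reactions) and ``iJO1366`` are available
    without network access.
    """
    import importlib.resources

    fname = {"e_coli_core": "textbook.xml.gz", "iJO1366": "iJO1366.xml.gz"}.get(name)
    if fname is None:
        raise ValueError(f"no bundled model named {name!r}")
    data_dir = importlib.resources.files("cobra") / "data"
    return read_model(str(data_dir / fname), format="sbml")


# ---------------------------------------------------------------------------
# Medium configuration and structural edits
# ---------------------------------------------------------------------------

def exchange_coefficient(model: MetabolicModel, rid: str) -> float:
    """Stoichiometric coefficient of the single metabolite of an exchange."""
    rxn = model.reaction(rid)
    if not rxn.is_exchange:
        raise ValueError(f"{rid} is not a single-metabolite exchange reaction")
    return next(iter(rxn.stoichiometry.values()))


def configure_medium(
    model: MetabolicModel,
    substrate_exchange: str,
    uptake_max: float,
    atpm_reaction: str | None = None,
    atpm_min: float = 0.0,
) -> MetabolicModel:
    """Bound substrate uptake magnitude and enforce ATP maintenance.

    All other exchange bounds are left as the model file states them (the
    file's own minimal-medium defaults); the function never invents medium
    composition.  Returns a new model with the substrate and maintenance
    reaction ids recorded in ``roles``.
    """
    if uptake_max < 0 or atpm_min < 0:
        raise ValueError("uptake_max and atpm_min must be non-negative")
    out = model.copy()
    c_s = exchange_coefficient(out, substrate_exchange)
    sub = out.reaction(substrate_exchange)
    if c_s < 0:  # BiGG style: uptake is negative flux
        sub.lower_bound = -uptake_max
    else:  # source style: uptake is positive flux
        sub.upper_bound = uptake_max
        sub.lower_bound = max(sub.lower_bound, 0.0)
    out.roles["substrate"] = substrate_exchange
    if atpm_reaction is not None:
        atpm = out.reaction(atpm_reaction)
        atpm.lower_bound = atpm_min
        out.roles["atpm"] = atpm_reaction
    return out


def remove_reactions(
    model: MetabolicModel, ids: list[str], protected: frozenset[str] = frozenset()
) -> MetabolicModel:
    """Return a model without the named reaction columns (rows unchanged).

    Refuses to remove the configured substrate exchange, any reaction
    recorded in ``model.roles``, any id in ``protected``, or a reaction whose
    id names the biomass function.
    """
    forbidden = set(protected) | set(model.roles.values())
    for rid in ids:
        model.reaction(rid)  # raise on unknown ids first
        if rid in forbidden or "biomass" in rid.lower():
            raise ValueError(f"refusing to remove protected reaction {rid}")
    drop = set(ids)
    out = model.copy()
    out.reactions = [r for r in out.reactions if r.id not in drop]
    return MetabolicModel(
        id=out.id, metabolites=out.metabolites, reactions=out.reactions, roles=out.roles
    )


# ---------------------------------------------------------------------------
# LP layer (FBA / FVA / yields)
# ---------------------------------------------------------------------------

def _lp(
    model: MetabolicModel,
    c: np.ndarray,
    fixed: dict[int, float] | None = None,
    extra_A_ub: sparse.spmatrix | None = None,
    extra_b_ub: np.ndarray | None = None,
):
    """Minimize ``c @ v`` s.t. ``N v = 0``, bounds, optional extra rows."""
    lb, ub = model.bounds_arrays()
    if fixed:
        for j, val in fixed.items():
            lb[j] = ub[j] = val
    res = linprog(
        c,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        A_eq=model.N,
        b_eq=np.zeros(model.m),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def fba(
    model: MetabolicModel, objective: str, maximize: bool = True
) -> tuple[float, np.ndarray]:
    """Flux balance analysis: optimal objective flux and a witness vector."""
    j = model.reaction_index(objective)
    c = np.zeros(model.n)
    c[j] = -1.0 if maximize else 1.0
    res = _lp(model, c)
    if res.status != 0:
        raise InfeasibleModelError(
            f"FBA for {objective} failed (LP status {res.status})", res.status
        )
    return float(res.x[j]), res.x


def fva_max(model: MetabolicModel, reactions: list[str]) -> dict[str, float]:
    """Per-reaction LP maximum flux under the model constraints."""
    # Base feasibility once; each maximization is then an independent LP.
    res = _lp(model, np.zeros(model.n))
    if res.status != 0:
        raise InfeasibleModelError(
            f"base model infeasible (LP status {res.status})", res.status
        )
    out = {}
    for rid in reactions:
        j = model.reaction_index(rid)
        c = np.zeros(model.n)
        c[j] = -1.0
        r = _lp(model, c)
        if r.status != 0:
            raise InfeasibleModelError(
                f"FVA LP for {rid} failed (status {r.status})", r.status
            )
        out[rid] = float(r.x[j])
    return out


def reaction_rate_coefficients(
    model: MetabolicModel, rid: str, substrate_exchange: str
) -> tuple[int, float]:
    """Column index and sign mapping flux to the reaction's natural rate.

    The substrate exchange is measured in the uptake convention (rate
    ``c_S * v``); any other exchange in the export convention (``-c * v``);
    internal reactions (e.g. biomass) as the flux itself.
    """
    j = model.reaction_index(rid)
    rxn = model.reaction(rid)
    if rid == substrate_exchange:
        return j, exchange_coefficient(model, rid)
    if rxn.is_exchange:
        return j, -exchange_coefficient(model, rid)
    return j, 1.0


def substrate_uptake_max(model: MetabolicModel, substrate_exchange: str) -> float:
    """Maximum uptake magnitude allowed by the substrate exchange bounds."""
    c_s = exchange_coefficient(model, substrate_exchange)
    rxn = model.reaction(substrate_exchange)
    lb = max(rxn.lower_bound, -DEFAULT_INF)
    ub = min(rxn.upper_bound, DEFAULT_INF)
    return c_s * lb if c_s < 0 else c_s * ub


def theoretical_max_yield(
    model: MetabolicModel, objective: str, substrate_exchange: str
) -> float:
    """Maximum objective rate per unit substrate uptake at full uptake.

    Substrate uptake is fixed to the configured maximum ``r_S,max``; the LP
    maximizes the objective's natural rate; the result is divided by
    ``r_S,max``.  Units: mmol (or gdw for biomass) per mmol substrate.
    """
    r_s_max = substrate_uptake_max(model, substrate_exchange)
    if r_s_max <= 0:
        raise InfeasibleModelError("substrate uptake bound is zero; no yield defined")
    js = model.reaction_index(substrate_exchange)
    c_s = exchange_coefficient(model, substrate_exchange)
    j, sign = reaction_rate_coefficients(model, objective, substrate_exchange)
    c = np.zeros(model.n)
    c[j] = -sign  # maximize sign * v_j
    res = _lp(model, c, fixed={js: r_s_max / c_s})
    if res.status != 0:
        raise InfeasibleModelError(
            f"yield LP infeasible at fixed uptake (status {res.status})", res.status
        )
    return float(sign * res.x[j] / r_s_max)
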