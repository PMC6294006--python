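"""Dual (Farkas) MILP for joint selection of static knockouts and valves.

The design problem asks for a minimum-cardinality set of reaction
interventions, split into static knockouts (off in both states) and valves
(on in the growth state, off in the production state), such that

1. the *undesired* production-state region (low product yield at real
   uptake) becomes infeasible — certified through Farkas duality: the MILP
   carries dual variables ``u`` (steady state), ``vp``/``vn`` (column slacks
   released only for intervened reactions) and ``w >= 0`` (undesired rows)
   with the strict-infeasibility margin ``t^T w <= -c``;
2. a *desired* production-state flux vector ``r`` (high yield, maintenance
   met) remains feasible with all intervened reactions closed;
3. a *desired* growth-state flux vector ``f`` (high biomass yield) remains
   feasible with knockouts closed but valves open.

Binary variables: ``zp_i`` (all reactions) and ``zn_i`` (reversible only)
release positive/negative dual slack; ``z_i = zp_i + zn_i <= 1`` marks an
intervention; ``y_i`` marks availability in the growth state.  Valves are
``y_i = 1 & z_i = 1``, knockouts ``y_i = 0 & z_i = 1``.  The objective
minimizes ``sum z_i``; the number of valves ``sum_i [y_i - (1 - z_i)]`` is
capped (or fixed) at ``max_valves``.

Solved with HiGHS through ``scipy.optimize.milp``.  HiGHS is deterministic
for a fixed problem, so runs are reproducible per backend version; the
``seed`` field is recorded in outputs for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse
from scipy.optimize import milp, LinearConstraint, Bounds

from .model import MetabolicModel
from .scenario import DecouplingSpec, LinearRegion, build_regions


@dataclass
class SolverConfig:
    """Backend and formulation knobs for one design solve.

    ``M_dual`` bounds the dual slack variables (big-M linking to the
    indicator binaries); ``c`` is the strict Farkas margin (any positive
    value is equivalent up to dual scaling).  ``accept_feasible`` returns
    the incumbent when the time limit is hit instead of failing.
    """

    time_limit: float = 600.0
    mip_gap: float = 1e-4
    accept_feasible: bool = True
    seed: int = 0
    backend: str = "highs"
    M_dual: float = 1000.0
    c: float = 1.0
    max_valves: int = 3
    valve_count_mode: str = "le"  # "le" or "eq"
    knockout_blacklist: frozenset[str] = frozenset()
    valve_blacklist: frozenset[str] = frozenset()
    forced_valves: frozenset[str] = frozenset()
    forced_knockouts: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.max_valves < 0:
            raise ValueError("max_valves must be non-negative")
        if self.valve_count_mode not in ("le", "eq"):
            raise ValueError("valve_count_mode must be 'le' or 'eq'")
        if self.c <= 0:
            raise ValueError("Farkas margin c must be strictly positive")


@dataclass
class InterventionStrategy:
    """One solved design: intervention sets, witnesses and dual certificate."""

    knockouts: frozenset[str]
    valves: frozenset[str]
    objective: int
    status: str  # optimal | feasible | infeasible | timeout
    witness_production: dict[str, float] = field(default_factory=dict)
    witness_growth: dict[str, float] = field(default_factory=dict)
    dual_certificate: dict = field(default_factory=dict)
    mip_gap: float | None = None

    @property
    def interventions(self) -> frozenset[str]:
        return self.knockouts | self.valves

    def to_json(self) -> str:
        d = asdict(self)
        d["knockouts"] = sorted(self.knockouts)
        d["valves"] = sorted(self.valves)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "InterventionStrategy":
        d = json.loads(text)
        d["knockouts"] = frozenset(d["knockouts"])
        d["valves"] = frozenset(d["valves"])
        return cls(**d)


class _Rows:
    """Accumulates sparse constraint rows with per-row lower/upper bounds."""

    def __init__(self):
        self.r, self.c, self.v = [], [], []
        self.lo, self.hi = [], []

    def add(self, coefs: dict[int, float], lo: float, hi: float):
        i = len(self.lo)
        for j, val in coefs.items():
            if val != 0.0:
                self.r.append(i)
                self.c.append(j)
                self.v.append(float(val))
        self.lo.append(lo)
        self.hi.append(hi)

    def add_cols(self, i_offset_cols, vals, lo, hi):
        i = len(self.lo)
        self.r.extend([i] * len(vals))
        self.c.extend(i_offset_cols)
        self.v.extend(vals)
        self.lo.append(lo)
        self.hi.append(hi)


@dataclass
class ValveDesignProblem:
    """Assembled MILP with variable layout metadata and exclusion cuts."""

    model: MetabolicModel
    rows: _Rows
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    objective: np.ndarray
    slices: dict[str, slice]
    rev_pos: dict[int, int]  # reaction column -> position in Rev ordering
    cuts: list[tuple[dict[int, float], float, float]] = field(default_factory=list)
    n_binaries: int = 0

    def z_columns(self, j: int) -> list[int]:
        """MILP columns whose sum is z_j for reaction column j."""
        cols = [self.slices["zp"].start + j]
        if j in self.rev_pos:
            cols.append(self.slices["zn"].start + self.rev_pos[j])
        return cols


INF = np.inf


def build_problem(
    model: MetabolicModel,
    undesired: LinearRegion,
    desired_prod: LinearRegion,
    desired_growth: LinearRegion,
    cfg: SolverConfig,
) -> ValveDesignProblem:
    """Assemble the dual MILP from the model and the three regions.

    Constraint blocks (v = [u, vp_Irr, vp_Rev, vn_Rev, w, r, f, zp, zn, y]):

    * dual feasibility:  ``N_Irr^T u + vp_Irr + T_Irr^T w >= 0`` and
      ``N_Rev^T u + vp_Rev - vn_Rev + T_Rev^T w = 0``;
    * Farkas margin:     ``t^T w <= -c`` with ``w >= 0``;
    * production state:  ``N r = 0``, ``D r <= d``;
    * growth state:      ``N f = 0``, ``G f <= g``;
    * knockout linking:  ``(1 - z_i) a_i <= r_i <= (1 - z_i) b_i``;
    * valve linking:     ``y_i >= 1 - z_i``, ``y_i g_i <= f_i <= y_i d_i``;
    * valve budget:      ``sum_i [y_i - (1 - z_i)] {<=,=} max_valves``;
    * indicator big-M:   ``vp <= M zp``, ``vn <= M zn``; ``zp + zn <= 1``.
    """
    n, m = model.n, model.m
    N = model.N.tocsc()
    T = undesired.matrix.tocsc()
    if T.shape[1] != n or desired_prod.matrix.shape[1] != n or desired_growth.matrix.shape[1] != n:
        raise ValueError("region column count does not match the model")
    tT = undesired.n_rows
    lb, ub = model.bounds_arrays(clip=True)
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise AssertionError("infinite bound reached the MILP after clipping")

    irr = model.irr_index
    rev = model.rev_index
    nI, nR = len(irr), len(rev)
    rev_pos = {int(j): k for k, j in enumerate(rev)}

    # variable layout
    names = ["u", "vp_irr", "vp_rev", "vn_rev", "w", "r", "f", "zp", "zn", "y"]
    sizes = [m, nI, nR, nR, tT, n, n, n, nR, n]
    slices, off = {}, 0
    for nm, sz in zip(names, sizes):
        slices[nm] = slice(off, off + sz)
        off += sz
    nvar = off

    var_lb = np.full(nvar, -INF)
    var_ub = np.full(nvar, INF)
    for nm in ("vp_irr", "vp_rev", "vn_rev", "w"):
        var_lb[slices[nm]] = 0.0
        var_ub[slices[nm]] = cfg.M_dual if nm != "w" else INF
    var_lb[slices["r"]], var_ub[slices["r"]] = lb, ub
    var_lb[slices["f"]], var_ub[slices["f"]] = lb, ub
    for nm in ("zp", "zn", "y"):
        var_lb[slices[nm]] = 0.0
        var_ub[slices[nm]] = 1.0
    integrality = np.zeros(nvar)
    for nm in ("zp", "zn", "y"):
        integrality[slices[nm]] = 1

    objective = np.zeros(nvar)
    objective[slices["zp"]] = 1.0
    objective[slices["zn"]] = 1.0

    ko_black = {model.reaction_index(rid) for rid in cfg.knockout_blacklist}
    valve_black = {model.reaction_index(rid) for rid in cfg.valve_blacklist}
    forced = {model.reaction_index(rid) for rid in cfg.forced_valves}
    forced_ko = {model.reaction_index(rid) for rid in cfg.forced_knockouts}
    if (forced | forced_ko) & ko_black:
        raise ValueError("a forced intervention is also knockout-blacklisted")
    if forced & forced_ko:
        raise ValueError("a reaction cannot be both a forced valve and knockout")

    zp0, zn0, y0 = slices["zp"].start, slices["zn"].start, slices["y"].start
    u0, w0 = slices["u"].start, slices["w"].start
    r0, f0 = slices["r"].start, slices["f"].start

    rows = _Rows()

    def z_cols(j):
        cols = [zp0 + j]
        if j in rev_pos:
            cols.append(zn0 + rev_pos[j])
        return cols

    # (i) dual feasibility rows, one per reaction column
    for k, j in enumerate(irr):
        cols = [u0 + i for i in N.indices[N.indptr[j]:N.indptr[j + 1]]]
        vals = list(N.data[N.indptr[j]:N.indptr[j + 1]])
        cols += [w0 + i for i in T.indices[T.indptr[j]:T.indptr[j + 1]]]
        vals += list(T.data[T.indptr[j]:T.indptr[j + 1]])
        cols.append(slices["vp_irr"].start + k)
        vals.append(1.0)
        rows.add_cols(cols, vals, 0.0, INF)
    for k, j in enumerate(rev):
        cols = [u0 + i for i in N.indices[N.indptr[j]:N.indptr[j + 1]]]
        vals = list(N.data[N.indptr[j]:N.indptr[j + 1]])
        cols += [w0 + i for i in T.indices[T.indptr[j]:T.indptr[j + 1]]]
        vals += list(T.data[T.indptr[j]:T.indptr[j + 1]])
        cols += [slices["vp_rev"].start + k, slices["vn_rev"].start + k]
        vals += [1.0, -1.0]
        rows.add_cols(cols, vals, 0.0, 0.0)

    # (ii) Farkas margin t^T w <= -c
    rows.add({w0 + i: undesired.rhs[i] for i in range(tT)}, -INF, -cfg.c)

    # (iii) production state: N r = 0, D r <= d
    Ncsr = N.tocsr()
    for i in range(m):
        cols = [r0 + j for j in Ncsr.indices[Ncsr.indptr[i]:Ncsr.indptr[i + 1]]]
        vals = list(Ncsr.data[Ncsr.indptr[i]:Ncsr.indptr[i + 1]])
        rows.add_cols(cols, vals, 0.0, 0.0)
    Dcsr = desired_prod.matrix.tocsr()
    for i in range(desired_prod.n_rows):
        cols = [r0 + j for j in Dcsr.indices[Dcsr.indptr[i]:Dcsr.indptr[i + 1]]]
        vals = list(Dcsr.data[Dcsr.indptr[i]:Dcsr.indptr[i + 1]])
        rows.add_cols(cols, vals, -INF, float(desired_prod.rhs[i]))

    # (iv) growth state: N f = 0, G f <= g
    for i in range(m):
        cols = [f0 + j for j in Ncsr.indices[Ncsr.indptr[i]:Ncsr.indptr[i + 1]]]
        vals = list(Ncsr.data[Ncsr.indptr[i]:Ncsr.indptr[i + 1]])
        rows.add_cols(cols, vals, 0.0, 0.0)
    Gcsr = desired_growth.matrix.tocsr()
    for i in range(desired_growth.n_rows):
        cols = [f0 + j for j in Gcsr.indices[Gcsr.indptr[i]:Gcsr.indptr[i + 1]]]
        vals = list(Gcsr.data[Gcsr.indptr[i]:Gcsr.indptr[i + 1]])
        rows.add_cols(cols, vals, -INF, float(desired_growth.rhs[i]))

    for j in range(n):
        zc = z_cols(j)
        # (v) knockout linking on r
        row = {r0 + j: 1.0}
        for cjz in zc:
            row[cjz] = ub[j]
        rows.add(row, -INF, ub[j])
        row = {r0 + j: 1.0}
        for cjz in zc:
            row[cjz] = lb[j]
        rows.add(row, lb[j], INF)
        # (vi) valve linking: y >= 1 - z ; y*lb <= f <= y*ub
        row = {y0 + j: 1.0}
        for cjz in zc:
            row[cjz] = 1.0
        rows.add(row, 1.0, INF)
        rows.add({f0 + j: 1.0, y0 + j: -ub[j]}, -INF, 0.0)
        rows.add({f0 + j: 1.0, y0 + j: -lb[j]}, 0.0, INF)

    # (vii) valve budget: sum_i (y_i + z_i) - n {<=,=} max_valves
    budget = {y0 + j: 1.0 for j in range(n)}
    budget.update({zp0 + j: 1.0 for j in range(n)})
    for k in range(nR):
        budget[zn0 + k] = 1.0
    target = float(n + cfg.max_valves)
    if cfg.valve_count_mode == "eq":
        rows.add(budget, target, target)
    else:
        rows.add(budget, -INF, target)

    # (viii) indicator big-M linking and reversible exclusivity
    for k, j in enumerate(irr):
        rows.add({slices["vp_irr"].start + k: 1.0, zp0 + j: -cfg.M_dual}, -INF, 0.0)
    for k, j in enumerate(rev):
        rows.add({slices["vp_rev"].start + k: 1.0, zp0 + j: -cfg.M_dual}, -INF, 0.0)
        rows.add({slices["vn_rev"].start + k: 1.0, zn0 + k: -cfg.M_dual}, -INF, 0.0)
        rows.add({zp0 + j: 1.0, zn0 + k: 1.0}, -INF, 1.0)

    # blacklists and forced valves via bound fixing / extra rows
    for j in ko_black:
        var_ub[zp0 + j] = 0.0
        if j in rev_pos:
            var_ub[zn0 + rev_pos[j]] = 0.0
        var_lb[y0 + j] = 1.0
    for j in valve_black:
        row = {y0 + j: 1.0}
        for cjz in z_cols(j):
            row[cjz] = 1.0
        rows.add(row, -INF, 1.0)  # forbid y=1 & z=1
    for j in forced:
        var_lb[y0 + j] = 1.0
        rows.add({cjz: 1.0 for cjz in z_cols(j)}, 1.0, 1.0)
    for j in forced_ko:
        var_ub[y0 + j] = 0.0
        rows.add({cjz: 1.0 for cjz in z_cols(j)}, 1.0, 1.0)
    if forced:
        # restrict valves to the forced set: elsewhere y = 1 - z exactly
        for j in range(n):
            if j in forced:
                continue
            row = {y0 + j: 1.0}
            for cjz in z_cols(j):
                row[cjz] = 1.0
            rows.add(row, -INF, 1.0)

    prob = ValveDesignProblem(
        model=model,
        rows=rows,
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
        objective=objective,
        slices=slices,
        rev_pos=rev_pos,
        n_binaries=int(integrality.sum()),
    )
    return prob


def add_exclusion_cut(
    problem: ValveDesignProblem, strategy: InterventionStrategy
) -> ValveDesignProblem:
    """Exclude the strategy's intervention support from future solves.

    Appends ``sum_{i in support} z_i <= |support| - 1``; re-solving then
    yields a different support or infeasibility, enabling enumeration of
    alternative minimal designs.
    """
    support = strategy.interventions
    row: dict[int, float] = {}
    for rid in support:
        for col in problem.z_columns(problem.model.reaction_index(rid)):
            row[col] = 1.0
    problem.cuts.append((row, -INF, float(len(support) - 1)))
    return problem


_STATUS = {0: "optimal", 1: "timeout", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve(problem: ValveDesignProblem, cfg: SolverConfig) -> InterventionStrategy:
    """Solve the assembled MILP and extract the intervention strategy.

    An infeasible problem is a meaningful outcome (no design exists under
    the given thresholds/budget) and is returned as a strategy with status
    ``infeasible`` and empty intervention sets, not raised.
    """
    rows = problem.rows
    nrow = len(rows.lo) + len(problem.cuts)
    r_idx = list(rows.r)
    c_idx = list(rows.c)
    vals = list(rows.v)
    lo = list(rows.lo)
    hi = list(rows.hi)
    for row, rlo, rhi in problem.cuts:
        i = len(lo)
        for j, v in row.items():
            r_idx.append(i)
            c_idx.append(j)
            vals.append(v)
        lo.append(rlo)
        hi.append(rhi)
    A = sparse.csr_matrix(
        (vals, (r_idx, c_idx)), shape=(nrow, len(problem.objective))
    )
    res = milp(
        c=problem.objective,
        constraints=LinearConstraint(A, np.array(lo), np.array(hi)),
        integrality=problem.integrality,
        bounds=Bounds(problem.var_lb, problem.var_ub),
        options={
            "time_limit": cfg.time_limit,
            "mip_rel_gap": cfg.mip_gap,
            "presolve": True,
            "disp": False,
        },
    )
    status = _STATUS.get(res.status, "error")
    if res.x is None:
        if status == "timeout" and not cfg.accept_feasible:
            status = "timeout"
        return InterventionStrategy(
            knockouts=frozenset(),
            valves=frozenset(),
            objective=-1,
            status="infeasible" if status == "infeasible" else "timeout",
        )
    if status == "timeout" and cfg.accept_feasible:
        status = "feasible"

    s = problem.slices
    x = res.x
    model = problem.model
    zp = x[s["zp"]]
    zn = x[s["zn"]]
    y = x[s["y"]]
    zvals = zp.copy()
    for j, k in problem.rev_pos.items():
        zvals[j] += zn[k]
    kos, valves = set(), set()
    for j, rxn in enumerate(model.reactions):
        if zvals[j] > 0.5:
            (valves if y[j] > 0.5 else kos).add(rxn.id)
    rxn_ids = [r.id for r in model.reactions]
    return InterventionStrategy(
        knockouts=frozenset(kos),
        valves=frozenset(valves),
        objective=int(round(zvals.sum())),
        status=status,
        witness_production=dict(zip(rxn_ids, map(float, x[s["r"]]))),
        witness_growth=dict(zip(rxn_ids, map(float, x[s["f"]]))),
        dual_certificate={
            "u": list(map(float, x[s["u"]])),
            "vp_irr": list(map(float, x[s["vp_irr"]])),
            "vp_rev": list(map(float, x[s["vp_rev"]])),
            "vn_rev": list(map(float, x[s["vn_rev"]])),
            "w": list(map(float, x[s["w"]])),
        },
        mip_gap=float(res.mip_gap) if res.mip_gap is not None else None,
    )


def design_strategy(
    model: MetabolicModel, spec: DecouplingSpec, cfg: SolverConfig | None = None
):
    """High-level entry point: regions, blacklist defaults, build, solve.

    The substrate exchange, product exchange, biomass and ATP maintenance
    reactions are excluded from intervention candidacy by default (they
    define the phenotypes being designed for); extend or override through
    ``cfg.knockout_blacklist``.

    Returns ``(strategy, regions)`` where ``regions`` is the
    (undesired, desired production, desired growth) triple used.
    """
    if cfg is None:
        cfg = SolverConfig()
    regions = build_regions(model, spec)
    cfg = SolverConfig(
        **{
            **asdict(cfg),
            "knockout_blacklist": frozenset(cfg.knockout_blacklist)
            | spec.role_ids(),
            "valve_blacklist": frozenset(cfg.valve_blacklist),
            "forced_valves": frozenset(cfg.forced_valves),
        }
    )
    problem = build_problem(model, *regions, cfg)
    return solve(problem, cfg), regions
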