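"""Dual MILP assembly and solving, checked against the brute-force oracle."""

import numpy as np
import pytest
from scipy import sparse

from fluxvalves.milp import (
    SolverConfig,
    add_exclusion_cut,
    build_problem,
    design_strategy,
    solve,
)
from fluxvalves.scenario import LinearRegion, build_regions, build_undesired_region
from fluxvalves.toys import brute_force, default_candidates, make_toy
from fluxvalves.validation import verify_strategy


def _toy_setup(tag, **cfg_kw):
    toy = make_toy(tag)
    regions = build_regions(toy.model, toy.spec)
    cfg = SolverConfig(
        time_limit=60.0,
        knockout_blacklist=toy.spec.role_ids(),
        **cfg_kw,
    )
    return toy, regions, cfg


def test_variable_block_arithmetic(two_branch):
    """Continuous count m + |Irr| + 2|Rev| + rows(T) + 2n; binaries n + |Rev| + n."""
    toy = two_branch
    regions = build_regions(toy.model, toy.spec)
    cfg = SolverConfig()
    prob = build_problem(toy.model, *regions, cfg)
    n, m = toy.model.n, toy.model.m
    nI, nR = len(toy.model.irr_index), len(toy.model.rev_index)
    tT = regions[0].n_rows
    n_cont = m + nI + 2 * nR + tT + 2 * n
    n_bin = n + nR + n
    assert len(prob.objective) == n_cont + n_bin
    assert prob.n_binaries == n_bin


def test_milp_matches_oracle_on_all_toys(toy):
    """Optimal objective equals the brute-force minimum and the support is
    a member of the oracle's minimal set (the repo's central property)."""
    regions = build_regions(toy.model, toy.spec)
    cand = default_candidates(toy)
    oracle = brute_force(toy.model, regions, max_size=3, max_valves=3,
                         candidates=cand)
    cfg = SolverConfig(time_limit=60.0, max_valves=3,
                       knockout_blacklist=toy.spec.role_ids())
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.status == "optimal"
    assert strat.objective == oracle.min_objective
    assert strat.interventions in {s for s in oracle.minimal_supports}
    assert (strat.knockouts, strat.valves) in oracle.minimal_strategies
    report = verify_strategy(toy.model, strat, regions, toy.spec,
                             check_minimal=True)
    assert report.valid and report.minimal


def test_two_branch_single_biomass_valve(two_branch):
    """The minimal design is one valve on the biomass branch, no knockouts."""
    toy, regions, cfg = _toy_setup("two_branch", max_valves=3)
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.objective == 1
    assert strat.knockouts == frozenset()
    assert strat.valves == frozenset({"RB"})


def test_witnesses_satisfy_their_states(toy):
    """MILP witnesses obey steady state, bounds/cuts and their region rows."""
    regions = build_regions(toy.model, toy.spec)
    cfg = SolverConfig(time_limit=60.0, knockout_blacklist=toy.spec.role_ids())
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    model = toy.model
    r = np.array([strat.witness_production[x.id] for x in model.reactions])
    f = np.array([strat.witness_growth[x.id] for x in model.reactions])
    tol = 1e-6
    assert np.abs(model.N @ r).max() <= tol
    assert np.abs(model.N @ f).max() <= tol
    assert r[model.irr_index].min() >= -tol
    _, desired_prod, desired_growth = regions
    assert (desired_prod.matrix @ r <= desired_prod.rhs + tol).all()
    assert (desired_growth.matrix @ f <= desired_growth.rhs + tol).all()
    for rid in strat.interventions:
        assert abs(strat.witness_production[rid]) <= tol
    for rid in strat.knockouts:
        assert abs(strat.witness_growth[rid]) <= tol


def test_forced_valve_is_used_and_exclusive():
    toy, regions, cfg = _toy_setup(
        "shared_intermediate", forced_valves=frozenset({"RB"}), max_valves=3
    )
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.status == "optimal"
    assert strat.valves == frozenset({"RB"})  # no other valve may open
    assert "EX_O" in strat.knockouts


def test_forcing_an_unusable_valve_is_infeasible():
    # the product branch must stay open in the production state, so forcing
    # it closed there (as a valve) can never decouple
    toy, regions, cfg = _toy_setup("two_branch", forced_valves=frozenset({"RP"}))
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.status == "infeasible"
    assert strat.knockouts == frozenset() and strat.valves == frozenset()


def test_valve_budget_monotone():
    """Relaxing the valve budget can only improve the optimum."""
    objs = {}
    for k in (1, 2, 3):
        toy, regions, cfg = _toy_setup("bypass", max_valves=k)
        strat = solve(build_problem(toy.model, *regions, cfg), cfg)
        objs[k] = strat.objective if strat.status == "optimal" else np.inf
    assert objs[3] <= objs[2] <= objs[1]


def test_budget_zero_forces_pure_knockouts(two_branch):
    """max_valves = 0 turns every intervention into a static knockout; the
    two-branch toy then has no design (growth would die with its branch)."""
    toy, regions, cfg = _toy_setup("two_branch", max_valves=0)
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.status == "infeasible"


def test_equality_valve_count_mode():
    toy, regions, cfg = _toy_setup("bypass", max_valves=2,
                                   valve_count_mode="eq")
    strat = solve(build_problem(toy.model, *regions, cfg), cfg)
    assert strat.status == "optimal"
    assert len(strat.valves) == 2


def test_big_m_scaling_leaves_optimum_unchanged(toy):
    """x10 on the dual big-M must not change the optimum (no truncation)."""
    regions = build_regions(toy.model, toy.spec)
    objs = []
    for M in (1000.0, 10000.0):
        cfg = SolverConfig(time_limit=60.0, M_dual=M,
                           knockout_blacklist=toy.spec.role_ids())
        strat = solve(build_problem(toy.model, *regions, cfg), cfg)
        objs.append((strat.status, strat.objective))
    assert objs[0] == objs[1]


def test_exclusion_cuts_enumerate_oracle_minimum_supports():
    """Adding exclusion cuts until the objective degrades recovers exactly
    the oracle's minimum-cardinality supports."""
    toy, regions, cfg = _toy_setup("shared_intermediate", max_valves=3)
    cand = default_candidates(toy)
    oracle = brute_force(toy.model, regions, 3, 3, candidates=cand)
    min_supports = {s for s in oracle.minimal_supports
                    if len(s) == oracle.min_objective}
    prob = build_problem(toy.model, *regions, cfg)
    found = set()
    for _ in range(10):
        strat = solve(prob, cfg)
        if strat.status != "optimal" or strat.objective > oracle.min_objective:
            break
        found.add(strat.interventions)
        prob = add_exclusion_cut(prob, strat)
    assert found == min_supports


def test_excluding_unseen_support_keeps_optimum(two_branch):
    from fluxvalves.milp import InterventionStrategy

    toy, regions, cfg = _toy_setup("two_branch")
    prob = build_problem(toy.model, *regions, cfg)
    base = solve(prob, cfg)
    ghost = InterventionStrategy(
        knockouts=frozenset({"RP"}), valves=frozenset(), objective=1,
        status="optimal",
    )
    prob = add_exclusion_cut(prob, ghost)
    again = solve(prob, cfg)
    assert again.objective == base.objective


def test_fully_overlapping_regions_are_infeasible(two_branch):
    """If the undesired region IS the desired production region, nothing can
    cut one while keeping the other."""
    toy = two_branch
    regions = build_regions(toy.model, toy.spec)
    desired_prod = regions[1]
    overlap = LinearRegion(
        sparse.vstack([desired_prod.matrix,
                       build_undesired_region(toy.model, toy.spec).matrix[1]]),
        np.concatenate([desired_prod.rhs, [-toy.spec.r_s_min]]),
        "undesired_T",
    )
    cfg = SolverConfig(time_limit=60.0,
                       knockout_blacklist=toy.spec.role_ids())
    strat = solve(build_problem(toy.model, overlap, desired_prod, regions[2],
                                cfg), cfg)
    assert strat.status == "infeasible"


def test_region_dimension_mismatch_raises(two_branch, core_model, akg_spec):
    toy = two_branch
    regions = build_regions(toy.model, toy.spec)
    wrong = build_undesired_region(core_model, akg_spec)
    with pytest.raises(ValueError):
        build_problem(toy.model, wrong, regions[1], regions[2], SolverConfig())


def test_design_strategy_blacklists_role_reactions(toy):
    strat, regions = design_strategy(toy.model, toy.spec,
                                     SolverConfig(time_limit=60.0))
    assert strat.status == "optimal"
    assert not (strat.interventions & toy.spec.role_ids())
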