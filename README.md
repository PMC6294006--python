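# fluxvalves

Strain-design tool for **two-stage bioprocesses**: given a constraint-based
metabolic model, it finds a minimum-cardinality set of reaction
interventions — split into **static knockouts** (off always) and dynamically
switchable **valves** (on while growing, off while producing) — that
*decouples* a growth phenotype from a production phenotype.  After the
switch, the engineered network provably admits **no** steady-state flux
distribution with product yield below a chosen threshold, while before the
switch it still grows at near-maximal biomass yield.

It is aimed at metabolic engineers working with genome-scale or core
reconstructions (SBML L3+fbc or BiGG-style JSON, e.g. e_coli_core, iJO1366)
who want provable dynamic flux-redirection strategies rather than
growth-coupled static designs.

## The optimization problem

Let **N** be the m×n stoichiometric matrix, with flux bounds
α ≤ r ≤ β and irreversible reactions Irr (r_i ≥ 0).  Three polyhedra over
flux space are built from yield thresholds (resolved against LP theoretical
maxima):

* **undesired** T·r ≤ t — production-state fluxes with product yield
  r_P/r_S ≤ Y^P/S_min at substrate uptake r_S ≥ r_S,min;
* **desired production** D·r ≤ d — yield ≥ Y^P/S_min (plus a biomass-yield
  floor for *partial* decoupling), ATP maintenance and uptake cap;
* **desired growth** G·f ≤ g — biomass yield f_B/f_S ≥ Y^B/S_min, same
  maintenance/cap rows, on a second flux vector f.

Eliminating the undesired region is certified through Farkas duality: a
mixed-integer program carries dual variables (u, vp, vn, w ≥ 0) with the
strict margin tᵀw ≤ −c, where binary indicators z_i (z = zp + zn for
reversible reactions) release the dual column slack of intervened reactions
and simultaneously force r_i = 0.  Binary y_i marks availability in the
growth state (y_i ≥ 1 − z_i; y_i γ_i ≤ f_i ≤ y_i δ_i): valves are
{y=1, z=1}, knockouts {y=0, z=1}, and Σ_i [y_i − (1 − z_i)] is capped (or
fixed) at the valve budget.  The objective minimizes Σ z_i.  Any feasible
point is a *sound* design; optimality only minimizes intervention count.

Solved with HiGHS (`scipy.optimize.milp`).  Every returned strategy is
re-verified by an independent LP-only certificate (infeasibility of the cut
undesired system, feasibility of both desired states, worst-case product
yield at full uptake) that never consults the MILP solution.

## Worked example

Full decoupling of α-ketoglutarate (AKG) export on the bundled core
*E. coli* model, glucose uptake 10 mmol gdw⁻¹ h⁻¹, ATP maintenance
8.39 mmol gdw⁻¹ h⁻¹, 90 % yield thresholds in both states, at most three
valves:

```
$ fluxvalves -v solve --model e_coli_core --product EX_akg_e \
    --substrate EX_glc__D_e --biomass Biomass_Ecoli_core \
    --atpm ATPM --atpm-min 8.39 --uptake-max 10 \
    --mode full --max-valves 3 --out akg_demo
INFO fluxvalves: EX_akg_e: optimal objective=5 knockouts=['MDH', 'PYK', 'SUCCt3'] valves=['EX_co2_e', 'NH4t'] valid=True
```

Five interventions: knock out malate dehydrogenase, pyruvate kinase and a
succinate transporter permanently, and close CO₂ exchange and ammonium
transport only in the production state.  The validation report
(`akg_demo/EX_akg_e.validation.json`):

```json
{
  "desired_growth_feasible": true,
  "desired_prod_feasible": true,
  "guaranteed_min_product_yield": 1.0,
  "max_growth_state_biomass_yield": 0.08258192905969887,
  "minimal": true,
  "undesired_eliminated": true,
  "valid": true
}
```

Reading: after the switch the network *cannot* run any steady-state flux
with AKG yield below the threshold — in fact the worst case equals the
theoretical maximum yield of 1 mol/mol — and before the switch it grows at
0.0826 gdw/mmol, 94.5 % of the wild-type maximum (0.0874).  No intervention
is redundant.

The same machinery runs from Python:

```python
from fluxvalves import (load_example_model, configure_medium, DecouplingSpec,
                        SolverConfig, design_strategy, verify_strategy)

model = configure_medium(load_example_model("e_coli_core"),
                         "EX_glc__D_e", 10, "ATPM", 8.39)
spec = DecouplingSpec(product_rxn="EX_akg_e", substrate_rxn="EX_glc__D_e",
                      biomass_rxn="Biomass_Ecoli_core", atpm_rxn="ATPM",
                      mode="full", uptake_max=10, atpm_min=8.39)
strategy, regions = design_strategy(model, spec, SolverConfig(max_valves=3))
report = verify_strategy(model, strategy, regions, spec)
```

Other subcommands: `model info|fva`, `targets` (organic, producible export
reactions with per-metabolite rationale), `screen` (resumable batch over a
target list, with valve-frequency and co-occurrence tables), `validate`,
`report`.

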