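# Methods

## Model representation and conventions

A model is an ordered metabolite list (rows of the sparse stoichiometric
matrix **N**) and reaction list (columns with bounds, mmol gdw⁻¹ h⁻¹).
A reaction is irreversible iff its lower bound is ≥ 0, and an exchange iff
its stoichiometry touches exactly one metabolite.  File I/O (SBML L3 + fbc,
BiGG JSON) is delegated to cobrapy; all LP work — FBA, FVA, theoretical
yields, and every verification certificate — is done directly with scipy's
HiGHS `linprog` on our own arrays, keeping the optimization path independent
of cobrapy's solver stack (which the test suite then uses as a second
opinion).

Sign handling: an exchange with coefficient c on its metabolite adds c·v of
it to the network per unit flux, so the substrate uptake rate is r_S = c_S·v_S
(for BiGG exchanges c_S = −1 and uptake flux is negative); product and
biomass rates are measured in the forward/export direction.  All region rows
are written on raw fluxes with these signs folded in, which lets toy models
use irreversible source-style exchanges while genome-scale BiGG models keep
their native convention.

Infinite bounds are clipped to ±1000 (the BiGG convention) before any MILP
construction; the knockout/valve linking rows need finite coefficients.
Feasibility tolerance is 1e-9, producibility tolerance 1e-6 (a flux must
clear numerical noise to count as producible).

## Two-state design problem

The decoupling specification carries four reaction roles (product export,
substrate exchange, biomass, ATP maintenance), the mode (full: zero growth
allowed while producing; partial: a minimum production-state biomass yield,
gdw/mmol), fractional yield thresholds, the uptake cap r_S,max and the
maintenance minimum.  Fractions are resolved to absolute yields at region
construction time by LP (fraction × theoretical maximum at uptake fixed to
r_S,max), so the emitted rows carry concrete coefficients and can be audited
as TSV.

Defaults follow the reference operating points for these organisms: glucose
uptake 10 mmol gdw⁻¹ h⁻¹; ATP maintenance 8.39 (core *E. coli*), 3.15
(iJO1366) or 1 (iMM904); full decoupling at 90 % of theoretical maximum
product yield with ≥ 90 % of maximum biomass yield in the growth state;
partial decoupling at 70 % product yield with a 0.01 gdw/mmol biomass floor
(0.001 for yeast).  The spec exposes the analytic identity
`implied_growth_rate_state2 = yield_floor × uptake_max` (0.1 h⁻¹ and
0.01 h⁻¹ respectively), asserted during threshold resolution.

**Inhomogeneity of the undesired region.** A bare low-yield row has zero
right-hand side; the resulting cone contains the zero flux and admits no
strictly negative Farkas certificate, so the dual margin tᵀw ≤ −c would be
unsatisfiable.  The undesired region therefore always includes a minimum-
uptake row r_S ≥ r_S,min (default r_S,min = r_S,max, i.e. yield judged at
full uptake), giving t a negative entry.  This matches standard
constrained-MCS practice: the region to eliminate is "low yield at real
uptake", not "low yield at rest".

The growth-state biomass threshold is evaluated as a *yield* at capped
uptake; at fixed r_S,max yield and growth-rate formulations coincide, and
the yield form stays meaningful if the cap is changed.

ATP maintenance and uptake-cap rows are attached to both desired regions
(not the global bounds) so each state carries one self-contained constraint
block; the model-level ATPM lower bound set by `configure_medium`
additionally applies to every LP on the bounded system.

## The dual MILP

Variables: continuous u (free, one per metabolite), vp over all reactions
and vn over reversible ones (∈ [0, M]), w ≥ 0 (one per undesired row),
production flux r and growth flux f; binaries zp (all), zn (reversible),
y (all).  Constraints:

* dual feasibility  N_Irrᵀu + vp_Irr + T_Irrᵀw ≥ 0,
  N_Revᵀu + vp_Rev − vn_Rev + T_Revᵀw = 0, and the margin tᵀw ≤ −c;
* production state  N·r = 0, D·r ≤ d, (1−z_i)α_i ≤ r_i ≤ (1−z_i)β_i;
* growth state  N·f = 0, G·f ≤ g, y_iγ_i ≤ f_i ≤ y_iδ_i, y_i ≥ 1−z_i;
* budget  Σ_i [y_i − (1−z_i)] ≤ max_valves (or =, for exhaustive
  fixed-valve-count searches);
* indicators  vp_i ≤ M·zp_i, vn_i ≤ M·zn_i, zp_i + zn_i ≤ 1.

Minimizing Σ z_i yields the fewest interventions; valves are the reactions
with y = z = 1, knockouts y = 0, z = 1.

Numerical choices:

* **c = 1.**  The dual cone is scale-invariant, so any positive margin is
  equivalent; fixed for reproducibility.
* **M = 1000** for dual slacks, with a ×10 stability test in the suite: on
  every toy the optimum is unchanged under M → 10M, the standard detector
  for big-M truncation.
* **One-way indicator linking only** (vp ≤ M·zp, not the converse): a
  spurious z = 1 with zero dual value is never optimal under min Σz, and
  the independent verifier would catch an unsound strategy regardless.
* **Reversible interventions** use one indicator per direction with
  zp + zn ≤ 1: the dual slack of a cut reversible column needs one sign at
  a time, and z = zp + zn counts it once.  Valve semantics are
  per-reaction, not per-direction.
* **Blacklist defaults.**  The four role reactions are excluded from
  intervention candidacy by the orchestration layer (`design_strategy`) —
  cutting the substrate, product, biomass or maintenance reaction is
  always either vacuous or self-defeating; the set is configurable.  An
  essentiality blacklist for valves in partial mode can be computed by a
  single-closure FBA screen (a model-based approximation of experimental
  essentiality; reactions with enforced nonzero flux, e.g. ATPM, count as
  essential by definition) or supplied as a file.
* **Forced interventions.**  A forced valve fixes z = y = 1 and restricts
  all other reactions to y = 1 − z (so the forced set is exactly the valve
  set — the per-valve screening mode); forced knockouts fix z = 1, y = 0.
* **Ties and timeouts.**  Among alternative optima the backend's incumbent
  is returned; HiGHS is deterministic per version, and the config's seed is
  recorded in outputs for provenance.  On hitting the time limit the
  incumbent is returned flagged `feasible` (any feasible point is a sound
  design); infeasibility is a meaningful result, returned as a status, not
  an exception.
* **No network compression.**  Problems are solved on the uncompressed
  stoichiometry; compressed formulations could return support-different but
  objective-equivalent solutions.

Alternative optima can be enumerated by exclusion cuts
(Σ_{support} z ≤ |support|−1) and re-solving.

## Independent verification

Every strategy is certified by plain LPs that never touch the MILP
solution: (1) the homogeneous undesired system {N·v = 0, v_Irr ≥ 0,
T·v ≤ t} with all intervened fluxes fixed to zero must be infeasible —
exactly the primal of the MILP's dual block, so agreement is two-sided
Farkas; (2) the bounded production state (interventions closed, D rows) and
(3) the bounded growth state (knockouts closed, valves open, G rows) must
be feasible.  "Closed" closes both directions of a reversible reaction,
mirroring z semantics.  The report also quantifies the worst-case product
yield at uptake fixed to r_S,max (deliberately without the D yield rows —
the point is what stoichiometry alone guarantees) and the maximum
growth-state biomass yield.  Set-minimality is checked per intervention:
reopening any single one must re-admit the undesired region (reopening can
only enlarge the desired sets, so that is the decisive test).

## Toy networks and the brute-force oracle

Four hand-built networks (≤ 12 reactions) provide exact ground truth: a
clean two-branch split, a carbon-lossy product bypass that must be
statically removed, a shared-precursor/overflow topology where a knockout
primes the valve, and a reversible interconversion exercising the signed
indicator pair.  Each carries a non-carbon energy cofactor consumed by a
maintenance reaction so the desired production region genuinely excludes
the zero flux; substrate enters through an irreversible source-style
exchange (bounds 0–10), keeping the two-branch toy all-irreversible.
Thresholds mirror the full-decoupling defaults (90 %/90 %, maintenance 1).

The oracle enumerates intervention supports in increasing cardinality over
the same candidate set the MILP sees, prunes supersets of accepted supports,
and checks every valve sub-assignment within the budget with the LP
verifier; a guard caps the enumeration size.  The suite's central property
is that on every toy the MILP optimum equals the oracle minimum and the
returned (knockout, valve) partition is a member of the oracle's minimal
set; with a zero valve budget and no growth region the same machinery
reduces to constrained minimal-cut-set enumeration, cross-checked support
by support through exclusion cuts.

What the toys do *not* emulate: cofactor/redox coupling across many
reactions, compartments, and the degenerate alternate-optima structure of
genome-scale networks.  Passing them shows the formulation and its duality
logic are implemented correctly, not that a particular organism-scale
design is biologically actionable; the core-model run plus the independent
certificate covers the realistic-model path.

## Problem sizes and scope

The bundled core *E. coli* model (72 metabolites, 95 reactions, 46
reversible) solves to optimality in seconds on one CPU with HiGHS; the
default time limit (600 s) and `accept_feasible` exist for genome-scale
models, where runs of this formulation historically used hours of
commercial-solver time per target.  The batch screen is sequential and
resumable; the full organism-wide product surveys from such screens are
outside the test scope, though `targets` + `screen` provide the machinery.
The co-occurrence adjacency matrix is emitted for external clustering
tools; no clustering is performed here (the published consensus-clustering
step is generic post-processing whose cluster-count rule is
under-specified).  Gene–protein–reaction mapping, heterologous pathway
insertion, thermodynamic constraints and kinetic simulation of the switch
are out of scope.

## Known limitations

* Bundled SBML distributions of the reference models carry no subsystem
  annotations; subsystem-grouped tables are fully populated only for models
  read from BiGG JSON.
* The undesired region is judged on the homogeneous cone (standard MCS
  semantics): reactions with enforced minimum flux lose that requirement
  inside the cone, which is conservative (the eliminated region is larger
  than the bounded one).
* The "organic" rule (contains carbon, minus a configurable CO₂/HCO₃⁻/CO/
  cyanide list) is a convention; published product counts depending on a
  different rule may differ, which is why the target list reports
  per-metabolite rationale rather than a bare count.
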