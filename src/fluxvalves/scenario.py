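"""Decoupling specification and polyhedral flux-region construction.

A two-state strain design is specified by the roles of four reactions
(product export, substrate exchange, biomass, ATP maintenance) plus yield
thresholds, and compiled into three polyhedral constraint blocks over the
flux space, each in the canonical form ``matrix @ v <= rhs``:

* the **undesired region** ``(T, t)`` — production-state flux vectors whose
  product yield falls below the threshold at non-trivial substrate uptake;
  the interventions must render this region infeasible;
* the **desired production region** ``(D, d)`` — high product yield (and,
  for partial decoupling, a minimum biomass yield), ATP maintenance met,
  uptake within the cap;
* the **desired growth region** ``(G, g)`` — high biomass yield, ATP
  maintenance met, uptake within the cap, evaluated on the growth-state
  flux vector.

Fractional thresholds are resolved to absolute yields at construction time
by LP (fraction x theoretical maximum), so region rows carry concrete
coefficients.

Note on the inhomogeneity of the undesired region: a bare yield row with a
zero right-hand side describes a cone containing the zero flux vector, and
a cone admits no strictly-negative Farkas certificate.  The region therefore
always carries a second row enforcing a minimum substrate uptake
``r_S >= r_S,min`` (default: the uptake cap itself), which excludes the
trivial zero flux and makes the dual margin constraint satisfiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .model import (
    MetabolicModel,
    exchange_coefficient,
    reaction_rate_coefficients,
    theoretical_max_yield,
    PRODUCIBILITY_TOL,
)


@dataclass(frozen=True)
class DecouplingSpec:
    """Roles, thresholds and rate limits defining both metabolic states.

    Parameters
    ----------
    product_rxn, substrate_rxn, biomass_rxn:
        Reaction ids for the product export, substrate exchange and biomass
        function.
    atpm_rxn:
        ATP maintenance reaction id, or ``None`` for models without one.
    mode:
        ``"full"`` — zero growth allowed in the production state;
        ``"partial"`` — a minimum biomass yield is retained while producing.
    min_product_fraction:
        Production-state product-yield threshold as a fraction of the
        theoretical maximum (used for both the undesired cutoff and the
        desired floor).
    min_biomass_yield_state2:
        Absolute biomass yield floor in the production state, gdw/mmol
        substrate (partial mode only; must be 0 in full mode).
    min_biomass_fraction_state1:
        Growth-state biomass-yield floor as a fraction of the theoretical
        maximum biomass yield.
    uptake_max:
        Substrate uptake cap r_S,max, mmol gdw^-1 h^-1.
    atpm_min:
        Minimum ATP maintenance flux enforced in both states.
    min_uptake_undesired:
        Minimum uptake r_S,min defining "non-trivial uptake" in the
        undesired region; defaults to ``uptake_max``.
    """

    product_rxn: str
    substrate_rxn: str
    biomass_rxn: str
    atpm_rxn: str | None = None
    mode: str = "full"
    min_product_fraction: float = 0.9
    min_biomass_yield_state2: float = 0.0
    min_biomass_fraction_state1: float = 0.9
    uptake_max: float = 10.0
    atpm_min: float = 0.0
    min_uptake_undesired: float | None = None

    def __post_init__(self):
        if self.mode not in ("full", "partial"):
            raise ValueError(f"mode must be 'full' or 'partial', got {self.mode!r}")
        for name in ("min_product_fraction", "min_biomass_fraction_state1"):
            frac = getattr(self, name)
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {frac}")
        if self.mode == "full" and self.min_biomass_yield_state2 != 0:
            raise ValueError("full decoupling requires min_biomass_yield_state2 == 0")
        if self.mode == "partial" and self.min_biomass_yield_state2 <= 0:
            raise ValueError("partial decoupling requires min_biomass_yield_state2 > 0")
        if self.uptake_max <= 0:
            raise ValueError("uptake_max must be positive")
        if self.atpm_min < 0:
            raise ValueError("atpm_min must be non-negative")
        r_s_min = self.r_s_min
        if not (0 < r_s_min <= self.uptake_max):
            raise ValueError("min_uptake_undesired must lie in (0, uptake_max]")

    @property
    def r_s_min(self) -> float:
        return (
            self.uptake_max
            if self.min_uptake_undesired is None
            else self.min_uptake_undesired
        )

    @property
    def implied_growth_rate_state2(self) -> float:
        """Growth rate (h^-1) implied by the production-state biomass-yield
        floor at maximum uptake: yield (gdw/mmol) x uptake (mmol gdw^-1 h^-1)."""
        return self.min_biomass_yield_state2 * self.uptake_max

    def role_ids(self) -> frozenset[str]:
        ids = {self.product_rxn, self.substrate_rxn, self.biomass_rxn}
        if self.atpm_rxn is not None:
            ids.add(self.atpm_rxn)
        return frozenset(ids)


@dataclass
class LinearRegion:
    """A polyhedral constraint block ``matrix @ v <= rhs`` over reaction space."""

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    label: str
    row_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = sparse.csr_matrix(self.matrix)
        self.rhs = np.asarray(self.rhs, dtype=float)
        if self.matrix.shape[0] != self.rhs.shape[0]:
            raise ValueError("row count of matrix and rhs differ")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def _rate_row(model, rid, substrate, scale=1.0):
    """Sparse row contribution: scale * (natural rate of reaction rid)."""
    j, sign = reaction_rate_coefficients(model, rid, substrate)
    return j, scale * sign


class ProductNotProducibleError(RuntimeError):
    """Theoretical maximum product yield is zero; no threshold can be set."""


def resolve_thresholds(model: MetabolicModel, spec: DecouplingSpec) -> dict[str, float]:
    """Resolve fractional thresholds to absolute yields via LP.

    Returns the theoretical maxima and the absolute minimum yields used in
    the region rows.  Also asserts the analytic consistency of the partial
    decoupling parameters (the production-state growth rate implied by the
    biomass-yield floor at maximum uptake).
    """
    y_p_theo = theoretical_max_yield(model, spec.product_rxn, spec.substrate_rxn)
    if y_p_theo <= PRODUCIBILITY_TOL:
        raise ProductNotProducibleError(
            f"product {spec.product_rxn} is not producible (theoretical max yield "
            f"{y_p_theo:.3g} <= {PRODUCIBILITY_TOL})"
        )
    y_b_theo = theoretical_max_yield(model, spec.biomass_rxn, spec.substrate_rxn)
    out = {
        "product_yield_theoretical_max": y_p_theo,
        "biomass_yield_theoretical_max": y_b_theo,
        "min_product_yield_state2": spec.min_product_fraction * y_p_theo,
        "min_biomass_yield_state2": spec.min_biomass_yield_state2,
        "min_biomass_yield_state1": spec.min_biomass_fraction_state1 * y_b_theo,
        "implied_growth_rate_state2": spec.implied_growth_rate_state2,
    }
    # Analytic sanity: yield floor x uptake cap = growth rate in the
    # production state; must be non-negative and below the uptake-scaled
    # theoretical biomass maximum for the region to be satisfiable at all.
    assert out["implied_growth_rate_state2"] >= 0
    if spec.mode == "partial":
        assert out["implied_growth_rate_state2"] <= y_b_theo * spec.uptake_max + 1e-12
    return out


def _common_state_rows(model, spec, rows, rhs, labels):
    """ATP maintenance and uptake-cap rows shared by both desired regions."""
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    if spec.atpm_rxn is not None and spec.atpm_min > 0:
        ja, sa = _rate_row(model, spec.atpm_rxn, spec.substrate_rxn)
        rows.append({ja: -sa})
        rhs.append(-spec.atpm_min)
        labels.append(f"atpm_min[{spec.atpm_rxn}>= {spec.atpm_min}]")
    rows.append({js: -c_s})  # r_S <= r_S,max with r_S = c_S * v_S
    rhs.append(spec.uptake_max)
    labels.append(f"uptake_cap[r_S<={spec.uptake_max}]")


def _to_region(model, rows, rhs, label, labels) -> LinearRegion:
    mat = sparse.lil_matrix((len(rows), model.n))
    for i, row in enumerate(rows):
        for j, coef in row.items():
            mat[i, j] = coef
    return LinearRegion(mat.tocsr(), np.array(rhs), label, labels)


def build_undesired_region(model: MetabolicModel, spec: DecouplingSpec) -> LinearRegion:
    """Undesired production-state region (T, t): low yield at real uptake.

    Row 1 encodes ``r_P - Y_min * r_S <= 0`` (product yield at or below the
    threshold); row 2 encodes ``r_S >= r_S,min`` as ``-r_S <= -r_S,min``,
    giving the right-hand side its strictly negative entry.
    """
    th = resolve_thresholds(model, spec)
    y_min = th["min_product_yield_state2"]
    jp, sp = _rate_row(model, spec.product_rxn, spec.substrate_rxn)
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    rows = [{jp: sp, js: -y_min * c_s}]
    rhs = [0.0]
    labels = [f"low_yield[r_P-{y_min:.6g}*r_S<=0]"]
    rows.append({js: -c_s})
    rhs.append(-spec.r_s_min)
    labels.append(f"uptake_min[r_S>={spec.r_s_min}]")
    return _to_region(model, rows, rhs, "undesired_T", labels)


def build_desired_production_region(
    model: MetabolicModel, spec: DecouplingSpec
) -> LinearRegion:
    """Desired production-state region (D, d): high yield, maintenance, cap.

    The yield block has one row (product) in full mode and two rows
    (product then biomass) in partial mode, followed by the ATP-maintenance
    and uptake-cap rows.
    """
    th = resolve_thresholds(model, spec)
    y_min = th["min_product_yield_state2"]
    jp, sp = _rate_row(model, spec.product_rxn, spec.substrate_rxn)
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    rows = [{jp: -sp, js: y_min * c_s}]  # Y_min * r_S - r_P <= 0
    rhs = [0.0]
    labels = [f"min_product_yield[{y_min:.6g}*r_S-r_P<=0]"]
    if spec.mode == "partial":
        jb, sb = _rate_row(model, spec.biomass_rxn, spec.substrate_rxn)
        yb = spec.min_biomass_yield_state2
        rows.append({jb: -sb, js: yb * c_s})
        rhs.append(0.0)
        labels.append(f"min_biomass_yield[{yb:.6g}*r_S-r_B<=0]")
    _common_state_rows(model, spec, rows, rhs, labels)
    return _to_region(model, rows, rhs, "desired_D", labels)


def build_desired_growth_region(
    model: MetabolicModel, spec: DecouplingSpec
) -> LinearRegion:
    """Desired growth-state region (G, g): high biomass yield, maintenance, cap."""
    th = resolve_thresholds(model, spec)
    yb_min = th["min_biomass_yield_state1"]
    if th["biomass_yield_theoretical_max"] <= PRODUCIBILITY_TOL:
        raise ProductNotProducibleError("biomass is not producible on this medium")
    jb, sb = _rate_row(model, spec.biomass_rxn, spec.substrate_rxn)
    js = model.reaction_index(spec.substrate_rxn)
    c_s = exchange_coefficient(model, spec.substrate_rxn)
    rows = [{jb: -sb, js: yb_min * c_s}]  # Y_min,1 * f_S - f_B <= 0
    rhs = [0.0]
    labels = [f"min_biomass_yield[{yb_min:.6g}*f_S-f_B<=0]"]
    _common_state_rows(model, spec, rows, rhs, labels)
    return _to_region(model, rows, rhs, "desired_G", labels)


def build_regions(
    model: MetabolicModel, spec: DecouplingSpec
) -> tuple[LinearRegion, LinearRegion, LinearRegion]:
    """Build (undesired, desired production, desired growth) in one call."""
    return (
        build_undesired_region(model, spec),
        build_desired_production_region(model, spec),
        build_desired_growth_region(model, spec),
    )


def region_to_tsv(region: LinearRegion, model: MetabolicModel) -> str:
    """Audit export: one row per constraint with nonzero coefficients."""
    lines = ["row_label\tcoefficients\trhs"]
    mat = region.matrix.tocsr()
    for i in range(region.n_rows):
        row = mat.getrow(i)
        coefs = ";".join(
            f"{model.reactions[j].id}:{v:.10g}"
            for j, v in zip(row.indices, row.data)
        )
        label = region.row_labels[i] if i < len(region.row_labels) else f"row{i}"
        lines.append(f"{label}\t{coefs}\t{region.rhs[i]:.10g}")
    return "\n".join(lines) + "\n"
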