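"""Shared fixtures: configured reference model, decoupling specs, toy nets.

The heavyweight objects (the core E. coli model and its solved designs) are
session-scoped so the MILP runs once and every test that needs the result
reuses it.
"""

import pytest

from fluxvalves import (
    DecouplingSpec,
    SolverConfig,
    configure_medium,
    design_strategy,
    load_example_model,
)
from fluxvalves.toys import ALL_TAGS, make_toy


@pytest.fixture(scope="session")
def core_model():
    """e_coli_core on glucose minimal medium: uptake 10, ATPM 8.39."""
    m = load_example_model("e_coli_core")
    return configure_medium(m, "EX_glc__D_e", 10.0, "ATPM", 8.39)


@pytest.fixture(scope="session")
def akg_spec():
    """Full decoupling of alpha-ketoglutarate export at 90%/90% thresholds."""
    return DecouplingSpec(
        product_rxn="EX_akg_e",
        substrate_rxn="EX_glc__D_e",
        biomass_rxn="Biomass_Ecoli_core",
        atpm_rxn="ATPM",
        mode="full",
        min_product_fraction=0.9,
        min_biomass_fraction_state1=0.9,
        uptake_max=10.0,
        atpm_min=8.39,
    )


@pytest.fixture(scope="session")
def akg_design(core_model, akg_spec):
    """Solved core-model AKG design: (strategy, regions, config)."""
    cfg = SolverConfig(max_valves=3, time_limit=600.0)
    strategy, regions = design_strategy(core_model, akg_spec, cfg)
    return strategy, regions, cfg


@pytest.fixture(params=ALL_TAGS)
def toy(request):
    return make_toy(request.param)


@pytest.fixture
def two_branch():
    return make_toy("two_branch")
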