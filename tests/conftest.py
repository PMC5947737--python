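import pytest

from c4budget import (
    DemandScenario,
    SinkRatios,
    Subtype,
    absorption_cascade,
    load_preset,
    scenario_budget,
    solve_cell_fluxes,
)

CASES = ["case_I", "case_II", "case_III", "case_IV"]


@pytest.fixture(scope="session")
def presets():
    return {name: load_preset(name) for name in CASES}


@pytest.fixture(scope="session")
def eff(presets):
    return presets["case_I"].efficiency


@pytest.fixture(scope="session")
def basic_scenario():
    """NADP/NAD-ME demand with no photorespiration or alternative sinks."""
    return DemandScenario(subtype=Subtype.NADP_ME)


@pytest.fixture(scope="session")
def sinks_scenario():
    """Same demand with the illustrative sink ratios enabled."""
    return DemandScenario(
        subtype=Subtype.NADP_ME,
        sinks=SinkRatios.illustrative(),
        sinks_enabled=True,
    )


@pytest.fixture(scope="session")
def basic_budget(basic_scenario, eff):
    return scenario_budget(basic_scenario, eff)


@pytest.fixture(scope="session")
def basic_solutions(presets, basic_budget, eff):
    """Cell-type solutions for the four species presets under the basic budget."""
    out = {}
    for name, preset in presets.items():
        optics = absorption_cascade(preset.leaf)
        out[name] = solve_cell_fluxes(
            basic_budget, optics, preset.photosystems, eff
        )
    return out
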