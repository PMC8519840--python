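import pytest

from nutrigeo.diet_design import STANDARD_RATIOS, build_diet_panel, equimolar_mix
from nutrigeo.intake_geometry import rail_from_diet


@pytest.fixture(scope="session")
def panel():
    """The seven-ratio diet panel at 0.5 mol/L sucrose, equimolar mix."""
    return build_diet_panel(STANDARD_RATIOS, sucrose_molarity=0.5, mix=equimolar_mix())


@pytest.fixture(scope="session")
def panel_by_id(panel):
    return {d.id: d for d in panel}


@pytest.fixture(scope="session")
def rails(panel):
    return [rail_from_diet(d) for d in panel]
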