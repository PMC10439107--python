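import pytest

from sweetdot import patterns


@pytest.fixture(scope="session")
def inks():
    return patterns.table_inks()


@pytest.fixture(scope="session")
def canonical_patterns():
    return {name: patterns.generate_pattern(name) for name in patterns.DESIGN_NAMES}


MICRO_DESIGNS = ("Homogeneous", "SpacedFull", "SpacedHalf", "SpacedQuarter")
DOTTED_DESIGNS = MICRO_DESIGNS + ("Centered", "Periphery")
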