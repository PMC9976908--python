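import pytest

from mpcleave.panel import build_panel
from mpcleave.simulate import (
    CleavageModel,
    HairpinDesign,
    LibraryConfig,
    design_hairpin,
    random_designs,
    simulate_experiment,
)


@pytest.fixture
def basic_panel():
    """Three tiny references plus a spike-in, with 30/25-nt flanks on one."""
    return build_panel(
        [
            ("refA", "ACGUACGUACGUACGUACGU", "AA" * 15, "CC" * 12 + "C", False),
            ("refB", "GGCCAAUUGGCCAAUUGGCC", "AU", "GC", False),
            ("spike", "ACUGGAUCCGGAUUCAGGCAUCG", "AAA", "CCC", True),
        ]
    )


@pytest.fixture
def designed_hairpin():
    """Default-geometry hairpin (16-bp lower, 25-bp upper stem) with truth table."""
    return design_hairpin(HairpinDesign(id="hp0", seed=11))


@pytest.fixture(scope="session")
def small_experiment():
    """A 4-reference, error-free simulated experiment shared across tests."""
    designs = random_designs(4, seed=21)
    model = CleavageModel()
    lib = LibraryConfig(depth_per_ref=300, spikein_reads=25, error_rate=0.0, seed=9)
    return simulate_experiment(designs, model, lib, control_depth_per_ref=60)
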