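import pytest

from foldkinetics import fixtures
from foldkinetics.calibration import FoldClass


@pytest.fixture(scope="session")
def panel_2s():
    """Two-state folding calibration panel with recomputed columns."""
    return fixtures.folding_panel_computed(FoldClass.TWO_STATE)


@pytest.fixture(scope="session")
def panel_n2s():
    """Non-two-state folding calibration panel with recomputed columns."""
    return fixtures.folding_panel_computed(FoldClass.NON_TWO_STATE)


@pytest.fixture(scope="session")
def policy():
    from foldkinetics.pipeline import default_policy

    return default_policy()
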