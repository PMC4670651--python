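import pytest

from aggimmuno import crosslink as cx
from aggimmuno import scenarios as scen


@pytest.fixture(scope="session")
def default_sweep():
    """Full default STC sweep (3 Ka x 3 Aga0 x 6 fractions, n=100, s=2/5/10)."""
    return cx.sweep()


@pytest.fixture(scope="session")
def processing_results():
    """ADA runs for baseline vs 16.6x internalization/degradation rates."""
    return scen.run_preset("processing-rates")


@pytest.fixture(scope="session")
def affinity_results():
    """ADA runs for the low-affinity baseline and its two aggregate mimics."""
    return scen.run_preset("epitope-affinity")


@pytest.fixture(scope="session")
def dose_ladder_results():
    """The three epitope-affinity conditions across the four-dose ladder."""
    return scen.run_preset("epitope-affinity-dose-ladder")


@pytest.fixture(scope="session")
def danger_results():
    """ADA runs across the danger-signal ladder."""
    return scen.run_preset("danger-signal-ladder")
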