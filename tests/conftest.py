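import pytest

from tal_biorefinery.fixtures import baseline_config
from tal_biorefinery.solubility import calibrated_tal_thermo


@pytest.fixture(scope="session")
def cfg():
    """Baseline biorefinery configuration (session-scoped; copy per test)."""
    return baseline_config()


@pytest.fixture(scope="session")
def tal_thermo():
    """TAL solubility thermodynamics calibrated to the observed extremes."""
    return calibrated_tal_thermo()


@pytest.fixture(scope="session")
def baseline_run(cfg):
    """Baseline simulate + TEA + LCA, shared across read-only tests."""
    from tal_biorefinery.pipeline import evaluate

    return evaluate(cfg, return_system=True)
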