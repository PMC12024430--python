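import pytest

import flashrod as fr
from flashrod.pipeline import ExperimentConfig, load_calibrated_yields


@pytest.fixture(scope="session")
def scheme():
    return fr.builtin_cell_scheme()


@pytest.fixture(scope="session")
def calibrated_yields():
    yields0 = load_calibrated_yields()
    assert yields0 is not None, "calibrated hand-off fixture missing"
    return yields0


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def n20_run(scheme, calibrated_yields, default_config):
    """Calibrated reference run: N=20 pulse, default cell water, to 1 s."""
    from flashrod.pipeline import run_endpoint

    series, ledger, pulse = run_endpoint(scheme, 20, calibrated_yields, default_config)
    return series, ledger, pulse


@pytest.fixture(scope="session")
def n30_run(scheme, calibrated_yields, default_config):
    from flashrod.pipeline import run_endpoint

    series, ledger, pulse = run_endpoint(scheme, 30, calibrated_yields, default_config)
    return series, ledger, pulse
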