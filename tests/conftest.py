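import numpy as np
import pytest

from phendo import calibrate_defaults, cell_from_config, fit_config_for


@pytest.fixture(scope="session")
def defaults():
    return calibrate_defaults()


@pytest.fixture(scope="session")
def cell37(defaults):
    return cell_from_config(defaults["37C"])


@pytest.fixture(scope="session")
def cell30(defaults):
    return cell_from_config(defaults["30C"])


@pytest.fixture(scope="session")
def cell_mouse(defaults):
    return cell_from_config(defaults["37C_mouse"])


@pytest.fixture(scope="session")
def fitcfg37():
    return fit_config_for("37C")


@pytest.fixture(scope="session")
def fitcfg30():
    return fit_config_for("30C")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
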