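import warnings

import pytest

from chemoflux.stability import build_diagram, classify_stability
from chemoflux.steady_state import ToxicitySpec, scan_auto
from chemoflux.toy import ToyParams, toy_as_generic_model, toy_thresholds

warnings.filterwarnings("ignore", message="clipping s")


@pytest.fixture(scope="session")
def toy_params():
    return ToyParams()


@pytest.fixture(scope="session")
def thresholds(toy_params):
    return toy_thresholds(toy_params)


@pytest.fixture(scope="session")
def toy_system(toy_params):
    """(model, medium, toxicity) of the solvable network, crowding encoding."""
    return toy_as_generic_model(toy_params)


@pytest.fixture(scope="session")
def toy_curve(toy_system):
    """Classified steady-state curve of the toy network, chemostat (phi=1)."""
    model, medium, tox = toy_system
    curve = scan_auto(model, medium, tox, phi=1.0, n=100)
    return classify_stability(curve)


@pytest.fixture(scope="session")
def toy_diagram(toy_system, toy_curve):
    model, medium, tox = toy_system
    return build_diagram(toy_curve, model, medium, tox)


@pytest.fixture(scope="session")
def toy_curve_notox(toy_system):
    model, medium, _ = toy_system
    curve = scan_auto(model, medium, ToxicitySpec.none(), phi=1.0, n=100)
    return classify_stability(curve)


@pytest.fixture(scope="session")
def toy_diagram_notox(toy_system, toy_curve_notox):
    model, medium, _ = toy_system
    return build_diagram(toy_curve_notox, model, medium, ToxicitySpec.none())
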