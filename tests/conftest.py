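import numpy as np
import pytest

from perisim.calibration import default_curve
from perisim.observer import Observer, PsychometricParams, SensitivitySurface
from perisim.patterns import build_pattern


@pytest.fixture(scope="session")
def curve():
    """Two-knot identity-gamma calibration fixture: {(0,0),(255,120)}."""
    return default_curve()


@pytest.fixture(scope="session")
def t24():
    return build_pattern("T-24", "OD")


@pytest.fixture(scope="session")
def t10():
    return build_pattern("T-10", "OD")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_flat_observer(
    peak=32.0, sigma=1.0, guess=0.0, lapse=0.0, fixation_sigma=0.0,
    eye="OD", blind_spot="default",
):
    """Flat-sensitivity observer; blind_spot='default' keeps the anatomical one."""
    if blind_spot == "default":
        bs = SensitivitySurface().blind_spot if eye == "OD" else ((-15.0, -2.0), 2.5)
    else:
        bs = blind_spot
    surface = SensitivitySurface(kind="flat", peak=peak, blind_spot=bs)
    params = PsychometricParams(sigma=sigma, guess_rate=guess, lapse_rate=lapse,
                                fixation_sigma=fixation_sigma)
    return Observer(surface=surface, params=params, eye=eye)


@pytest.fixture
def flat_observer():
    return make_flat_observer()


def deterministic_run(start, truth):
    """Run one staircase against a noiseless observer (seen iff level <= truth)."""
    from perisim.strategy import estimate, init_staircase, next_level, record_response

    st = init_staircase(0, start)
    while not st.finished:
        record_response(st, next_level(st) <= truth)
    return st, estimate(st)
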