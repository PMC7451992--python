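import logging

import pytest

import cardiorenal as cr
from cardiorenal.cardiac import beats_to_periodic_steady_state
from cardiorenal.virtual_patient import baseline_state, build_patient, get_preset

logging.getLogger("cardiorenal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params():
    return cr.default_parameters()


@pytest.fixture(scope="session")
def healthy_baseline():
    """Equilibrated healthy patient: (slow, fast, converged beat summary)."""
    slow, fast = baseline_state("healthy")
    p = build_patient(get_preset("healthy"))
    fast, bs = beats_to_periodic_steady_state(fast, p, slow)
    return slow, fast, bs


@pytest.fixture(scope="session")
def hypertensive_baseline():
    slow, fast = baseline_state("hypertensive")
    p = build_patient(get_preset("hypertensive"))
    fast, bs = beats_to_periodic_steady_state(fast, p, slow)
    return slow, fast, bs


@pytest.fixture(scope="session")
def hfref_baseline():
    slow, fast = baseline_state("hfref")
    p = build_patient(get_preset("hfref"))
    fast, bs = beats_to_periodic_steady_state(fast, p, slow)
    return slow, fast, bs


@pytest.fixture(scope="session")
def diabetic_hfref_baseline():
    slow, fast = baseline_state("diabetic_hfref")
    p = build_patient(get_preset("diabetic_hfref"))
    fast, bs = beats_to_periodic_steady_state(fast, p, slow)
    return slow, fast, bs
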