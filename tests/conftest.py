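import numpy as np
import pytest

from pahva.circulation import default_params, simulate
from pahva.datamodel import load_cohort_fixture


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def default_sim():
    """Periodic closed-loop run of the healthy-adult-like parameter set,
    shared across tests (the simulation is the expensive part)."""
    return simulate(default_params())


@pytest.fixture(scope="session")
def pah_patient_sim():
    """A mid-severity virtual patient with its periodic truth simulation."""
    from pahva.synthetic import sample_patient
    pat = sample_patient(7, 0.6)
    return pat, simulate(pat.truth)


def quadrature_loop(n=30, v_mean=90.0, v_amp=25.0, p_mean=45.0, p_amp=20.0,
                    harmonics=False):
    """Physiologically traversed PV loop: volume and pressure in quadrature
    (counter-clockwise loop enclosing maximal area at true alignment)."""
    th = 2.0 * np.pi * np.arange(n) / n
    v = v_mean + v_amp * np.cos(th)
    p = p_mean + p_amp * np.sin(th)
    if harmonics:
        v = v + 3.0 * np.cos(2.0 * th)
        p = p + 2.0 * np.sin(2.0 * th + 0.4)
    return v, p
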