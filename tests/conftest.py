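import numpy as np
import pytest

from tamoxmr.metabolites import ANALYTES, Measurement, PatientPanel, Status
from tamoxmr.star_allele import default_allele_definitions


@pytest.fixture(scope="session")
def defs():
    return default_allele_definitions()


@pytest.fixture
def rng():
    return np.random.default_rng(20150801)


def make_panel(patient_id="P1", **overrides):
    """A complete 13-analyte panel with simple defaults, overridable per test.

    Pass ``analyte=None`` for not-detected, a float for a quantified value,
    or a Measurement for full control.
    """
    defaults = {
        "tamoxifen": 170.0,
        "ndm_tam": 230.0,
        "z_endoxifen": 5.5,
        "z_4oh_tam": 2.5,
        "e_endoxifen": None,
        "4p_oh_tam": 3.1,
        "4p_oh_ndm_tam": 3.8,
        "tam_n_oxide": 13.5,
        "e_4oh_tam_o_gluc": 0.23,
        "ez_4oh_ndm_tam_gluc": 1.1,
        "ez_tam_n_gluc": 0.32,
        "e_a_oh_tam": 0.36,
        "z_a_oh_tam": None,
    }
    defaults.update(overrides)
    measurements = {}
    for a in ANALYTES:
        v = defaults[a]
        if isinstance(v, Measurement):
            measurements[a] = v
        elif v is None:
            measurements[a] = Measurement(None, Status.NOT_DETECTED)
        else:
            measurements[a] = Measurement(float(v), Status.QUANTIFIED)
    return PatientPanel(patient_id=patient_id, measurements=measurements)
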