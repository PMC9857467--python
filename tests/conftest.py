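import numpy as np
import pytest

from amblyosim import load_parameters, reference_draw


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def ref_draw(params):
    """All parameters pinned at their reference-case values."""
    return reference_draw(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_draw(params):
    """A draw with testing, incidence and mortality switched off: a healthy
    child accrues the full discounted QALY stream and zero cost."""
    d = reference_draw(params)
    d.p_well_child_visit = 0.0
    d.p_school_screen = 0.0
    d.p_optometric_exam_uptake = 0.0
    d.p_healthy_to_risk_factor = 0.0
    d.p_risk_factor_to_amblyopia = 0.0
    d.p_vision_loss_5_15 = 0.0
    d.p_vision_loss_16_18 = 0.0
    d.p_death_by_age = {a: 0.0 for a in d.p_death_by_age}
    return d
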